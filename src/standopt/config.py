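"""Shared configuration switches for structure computations.

The structure indexes and the objective carry a handful of behavioural
switches where the underlying definitions are ambiguous in the forestry
literature; each switch documents its default reading.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class StructureConfig:
    """Behavioural switches for index and objective computation.

    Parameters
    ----------
    no_overlap_value : float
        Crown overlap area returned for disjoint crown disks.  The literal
        convention is 1.0 m^2 (a unit "background shading" even for distant
        neighbours); set to 0.0 to make non-overlapping crowns contribute no
        competition.
    terrain_adjusted_layers : bool
        If True, vertical-layer assignment uses height + relative elevation;
        the default uses height only, matching the printed layer rule, while
        dominant height always includes the terrain term.
    freeze_deltas : bool
        If True, objective evaluations inside an optimizer reuse the
        standard deviations of the pre-move stand state instead of
        recomputing them per candidate state.
    mingling_include_reference : bool
        If True, the Simpson term of complete mingling counts the reference
        tree in the per-species counts; the default counts neighbours only.
    rfi_u_in_denominator : bool
        If True, the neighborhood-comparison factor of the replanting
        foreground index divides rather than multiplies (a suppressed
        virtual tree then scores lower); default follows the printed form
        (numerator).
    w_reference : float
        Target mean uniform-angle value for a random spatial pattern; used
        in the objective and the harvest/replant constraints.
    w_neighbours : int
        Number of nearest neighbours in the uniform angle index.  The
        classical construction uses the 4 nearest stems (standard angle
        72°), for which the random-pattern band [0.475, 0.517] holds.
    w_use_unit_neighbours : bool
        If True, W is instead computed over all Voronoi neighbours of the
        unit with standard angle 360/(n+1); this variant does not
        reproduce the classical random-pattern band.
    canopy_grid : float
        Grid resolution (m) of the deterministic canopy-cover union.
    reference_min_dbh : float
        Minimum DBH (cm) for a stem to serve as a reference tree in the
        index table and stand means.  At the default 0 every core stem is
        a reference tree.  Set to 6.0 (the diameter-class floor) to treat
        sub-threshold stems — freshly replanted 5 cm saplings — as
        neighbours only, the same role buffer trees play, until growth
        carries them past the measurement class floor.
    """

    no_overlap_value: float = 1.0
    terrain_adjusted_layers: bool = False
    freeze_deltas: bool = False
    mingling_include_reference: bool = False
    rfi_u_in_denominator: bool = False
    w_reference: float = 0.496
    w_neighbours: int = 4
    w_use_unit_neighbours: bool = False
    canopy_grid: float = 0.25
    reference_min_dbh: float = 0.0


DEFAULT_CONFIG = StructureConfig()
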