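"""Tunable parameters with field-standard defaults.

Every geometric threshold, weight and catalogue that the annotation
pipeline consumes lives here so that alternative conventions can be
swapped in without touching code.  Defaults are frozen for the golden
tests; change them only deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class InteractionConfig:
    """Geometric rules for the seven interaction types.

    Distances are heavy-atom to heavy-atom in angstroms; hydrogens are
    idealized from donor antecedents (no explicit H required).
    """

    hydrophobic_max: float = 4.5
    aromatic_f2f_max: float = 4.0          # ring-centroid distance
    aromatic_f2f_angle_max: float = 30.0   # inter-plane angle, degrees
    aromatic_e2f_max: float = 5.0
    aromatic_e2f_angle_range: tuple[float, float] = (60.0, 90.0)
    hbond_max: float = 3.5                 # donor heavy to acceptor heavy
    hbond_donor_angle_min: float = 120.0   # antecedent-donor-acceptor
    ionic_max: float = 4.5                 # opposite formal-charge centers


@dataclass(frozen=True)
class QualityConfig:
    """Linear-penalty quality score mapping structure defects to [0, 10]."""

    w_rmsd_anchor: float = 4.0
    w_rmsd_pocket: float = 1.0
    w_missing_residue: float = 0.4
    w_missing_atom: float = 0.1
    rmsd_anchor_offset: float = 0.8   # penalty-free anchor RMSD
    rmsd_pocket_offset: float = 2.2   # penalty-free pocket RMSD


@dataclass(frozen=True)
class AlignmentConfig:
    """Pairwise alignment of a kinase sequence against the master profile."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 80.0          # below this: "not a kinase domain"
    min_sequence_length: int = 50


@dataclass(frozen=True)
class ConformationConfig:
    """DFG / aC-helix / G-rich-loop classification parameters.

    The aC thresholds act on the Ca(F.xDFG.82)-Ca(E.aC.24) distance; they
    were fitted on the labeled synthetic corpus and frozen (see
    docs/methods.md for provenance).
    """

    alpha_c_in_max: float = 7.2      # d <= t1 -> aC-in
    alpha_c_outlike_max: float = 9.3  # t1 < d <= t2 -> aC-outlike
    asa_probe_radius: float = 1.4
    asa_sphere_points: int = 960


@dataclass(frozen=True)
class SubpocketConfig:
    """Probe-grid training and assignment parameters."""

    grid_spacing: float = 0.5
    contact_radius: float = 1.0
    min_ratio: float = 3.0           # positive:negative close-contact ratio
    top_k: int = 200                 # probes retained per label
    envelope_padding: float = 1.5


@dataclass(frozen=True)
class WaterConfig:
    assignment_radius: float = 1.5   # max water-to-centroid distance


@dataclass(frozen=True)
class EntityConfig:
    """Hetero-group classification catalogues and contact rule."""

    water_components: tuple[str, ...] = ("HOH", "DOD", "WAT")
    cofactor_components: tuple[str, ...] = (
        "ATP", "ADP", "AMP", "ANP", "AGS", "ACP", "ADN", "GTP", "GDP",
        "NAD", "NAP", "FAD", "FMN", "SAM", "SAH", "TPO", "SEP", "PTR",
    )
    metal_elements: tuple[str, ...] = (
        "MG", "MN", "ZN", "CA", "NA", "K", "FE", "CO", "NI", "CU", "CD", "LI", "SR", "CS",
    )
    halide_elements: tuple[str, ...] = ("F", "CL", "BR", "I")
    orthosteric_contact: float = 4.0  # heavy-atom contact to pocket residues


# Physicochemical property presets for ligand filtering.  Rule-of-five and
# rule-of-three bounds are the canonical ones; fragment-like follows the
# Congreve rule-of-three convention with a lower MW floor, lead-like the
# Teague/Oprea ranges.
PROPERTY_PRESETS: dict[str, dict[str, tuple[float | None, float | None]]] = {
    "rule-of-five": {"mw": (None, 500), "logp": (None, 5),
                     "hbd": (None, 5), "hba": (None, 10)},
    "rule-of-three": {"mw": (None, 300), "logp": (None, 3), "hbd": (None, 3),
                      "hba": (None, 3), "rotatable": (None, 3)},
    "fragment-like": {"mw": (120, 300), "logp": (None, 3), "hbd": (None, 3),
                      "hba": (None, 3), "rotatable": (None, 3)},
    "lead-like": {"mw": (200, 460), "logp": (-4.0, 4.2), "rotatable": (None, 10)},
}


@dataclass(frozen=True)
class Config:
    """Top-level configuration bundle for the annotation pipeline."""

    interactions: InteractionConfig = field(default_factory=InteractionConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    conformation: ConformationConfig = field(default_factory=ConformationConfig)
    subpockets: SubpocketConfig = field(default_factory=SubpocketConfig)
    waters: WaterConfig = field(default_factory=WaterConfig)
    entities: EntityConfig = field(default_factory=EntityConfig)

    def with_overrides(self, **sections) -> "Config":
        """Return a copy with whole sections replaced, e.g.
        ``cfg.with_overrides(quality=QualityConfig(w_missing_atom=0.2))``."""
        return replace(self, **sections)


DEFAULT_CONFIG = Config()
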