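"""Domain records shared across the vault, ranking, ORA and SPR stages.

All records are plain frozen dataclasses validated on construction; a
bad field raises :class:`ValidationError` naming the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "LEVELS",
    "LEVEL_RANK",
    "normalize_level",
    "ProteinRecord",
    "TMPrediction",
    "HealthyIHCObservation",
    "CancerIHCSummary",
    "RankKeys",
    "RankedTarget",
    "GeneSet",
    "SensorgramCycle",
    "KineticFit",
]


class ValidationError(ValueError):
    """A record field violated its invariant."""


#: Ordinal IHC scoring vocabulary (Human Protein Atlas convention),
#: lowest to highest.
LEVELS: Tuple[str, ...] = ("Not detected", "Low", "Medium", "High")

#: Ordinal rank of each level; comparisons go through this map, never
#: through string order.
LEVEL_RANK: Mapping[str, int] = {lvl: i for i, lvl in enumerate(LEVELS)}

_LEVEL_ALIASES = {lvl.lower().replace(" ", "").replace("_", ""): lvl for lvl in LEVELS}
_LEVEL_ALIASES["nd"] = "Not detected"

#: HPA-style cancer staining-intensity bins (Fig-2-style summaries).
INTENSITY_BINS: Tuple[str, ...] = ("negative", "weak", "moderate", "strong")

#: HPA-style staining-quantity (fraction of stained cells) bins.
QUANTITY_BINS: Tuple[str, ...] = ("<25%", "25-75%", ">75%")

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "XUBZ")


def normalize_level(level: str) -> str:
    """Return the canonical IHC level string for ``level``.

    Matching is case-insensitive and ignores spaces/underscores, so
    ``"not_detected"``, ``"NotDetected"`` and ``"NOT DETECTED"`` all map
    to ``"Not detected"``.
    """
    key = str(level).lower().replace(" ", "").replace("_", "")
    try:
        return _LEVEL_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"level: unknown IHC level {level!r}; expected one of {LEVELS}"
        ) from None


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its gene mapping and membrane annotation."""

    protein_id: str
    gene_id: str
    gene_symbol: str
    sequence: Optional[str] = None
    subcellular_locations: frozenset = field(default_factory=frozenset)
    is_transmembrane: bool = False

    def __post_init__(self):
        if not self.protein_id:
            raise ValidationError("protein_id: must be non-empty")
        if not self.gene_symbol:
            raise ValidationError("gene_symbol: must be non-empty")
        if self.sequence is not None:
            bad = set(self.sequence) - _AA_ALPHABET
            if bad:
                raise ValidationError(
                    f"sequence: invalid amino-acid letters {sorted(bad)}"
                )
        object.__setattr__(
            self, "subcellular_locations", frozenset(self.subcellular_locations)
        )


@dataclass(frozen=True)
class TMPrediction:
    """One predictor's transmembrane-segment call for one protein."""

    protein_id: str
    predictor: str
    n_segments: int
    segments: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self):
        if self.n_segments < 0:
            raise ValidationError("n_segments: must be >= 0")
        if self.segments is not None:
            segs = tuple(tuple(s) for s in self.segments)
            object.__setattr__(self, "segments", segs)
            if len(segs) != self.n_segments:
                raise ValidationError(
                    f"segments: {len(segs)} segments but n_segments={self.n_segments}"
                )
            prev_end = 0
            for start, end in segs:
                if start > end:
                    raise ValidationError(f"segments: start {start} > end {end}")
                if start <= prev_end:
                    raise ValidationError(
                        "segments: must be sorted and non-overlapping"
                    )
                prev_end = end


@dataclass(frozen=True)
class HealthyIHCObservation:
    """IHC level for one protein in one healthy tissue / cell type."""

    protein_id: str
    tissue: str
    cell_type: str
    level: str

    def __post_init__(self):
        object.__setattr__(self, "level", normalize_level(self.level))


@dataclass(frozen=True)
class CancerIHCSummary:
    """Patient-level IHC counts for one protein in one cancer type.

    ``intensity_counts`` / ``quantity_counts`` are optional finer-grained
    staining summaries; when present they must sum to the patient total.
    """

    protein_id: str
    cancer_type: str
    n_high: int
    n_medium: int
    n_low: int
    n_not_detected: int
    intensity_counts: Optional[Mapping[str, int]] = None
    quantity_counts: Optional[Mapping[str, int]] = None

    def __post_init__(self):
        counts = (self.n_high, self.n_medium, self.n_low, self.n_not_detected)
        if any(c < 0 for c in counts):
            raise ValidationError("n_*: patient counts must be >= 0")
        total = sum(counts)
        if total < 1:
            raise ValidationError("n_*: total patients must be >= 1")
        for name, bins, cts in (
            ("intensity_counts", INTENSITY_BINS, self.intensity_counts),
            ("quantity_counts", QUANTITY_BINS, self.quantity_counts),
        ):
            if cts is None:
                continue
            if set(cts) - set(bins):
                raise ValidationError(f"{name}: unknown bins {set(cts) - set(bins)}")
            if any(v < 0 for v in cts.values()):
                raise ValidationError(f"{name}: counts must be >= 0")
            if sum(cts.values()) != total:
                raise ValidationError(
                    f"{name}: sums to {sum(cts.values())}, expected {total}"
                )


@dataclass(frozen=True)
class RankKeys:
    """The four lexicographic ranking keys of a candidate target.

    k1
        Number of healthy tissues whose (collapsed) level is High or
        Medium — the combined off-target burden.
    k2, k3
        Number of healthy tissues at exactly High / exactly Medium.
    k4
        Fraction of cancer patients at High or Medium, in [0, 1].

    Under the per-tissue max collapse, ``k1 == k2 + k3``.
    """

    k1: int
    k2: int
    k3: int
    k4: float

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3) < 0:
            raise ValidationError("k1/k2/k3: must be >= 0")
        if not (0.0 <= self.k4 <= 1.0):
            raise ValidationError(f"k4: {self.k4} outside [0, 1]")

    def sort_key(self, gene_symbol: str) -> tuple:
        """Comparator tuple: k1, k2, k3 ascending; k4 descending; then symbol."""
        return (self.k1, self.k2, self.k3, -self.k4, gene_symbol)


@dataclass(frozen=True)
class RankedTarget:
    """One candidate in the ordered target list."""

    protein_id: str
    gene_symbol: str
    keys: RankKeys
    rank: int
    passed_tm_filter: bool
    data_gap: bool


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    name: str
    description: str
    genes: frozenset

    def __post_init__(self):
        if not self.name:
            raise ValidationError("name: must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"genes: gene set {self.name!r} is empty")


@dataclass(frozen=True)
class SensorgramCycle:
    """One SPR injection cycle's association + dissociation trace.

    Time axes are phase-local seconds: association t = 0 at injection
    start, dissociation t = 0 at injection end.  Responses are in
    resonance units (RU).  ``concentration`` is molar and must be 0 for
    blank (buffer-only) cycles and positive otherwise.
    """

    cycle_id: str
    concentration: float
    role: str  # "active" | "reference"
    t_assoc: np.ndarray
    r_assoc: np.ndarray
    t_dissoc: np.ndarray
    r_dissoc: np.ndarray
    is_blank: bool = False

    def __post_init__(self):
        if self.role not in ("active", "reference"):
            raise ValidationError(f"role: {self.role!r} not in {{active, reference}}")
        for name in ("t_assoc", "r_assoc", "t_dissoc", "r_dissoc"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for tname, rname in (("t_assoc", "r_assoc"), ("t_dissoc", "r_dissoc")):
            t, r = getattr(self, tname), getattr(self, rname)
            if t.shape != r.shape:
                raise ValidationError(f"{tname}/{rname}: length mismatch")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValidationError(f"{tname}: must be strictly increasing")
        if self.is_blank:
            if self.concentration != 0:
                raise ValidationError("concentration: blank cycles must have 0")
        elif self.concentration <= 0:
            raise ValidationError("concentration: must be > 0 for non-blank cycles")


@dataclass(frozen=True)
class KineticFit:
    """Result of a global 1:1 kinetic fit.

    ``chi2`` is the residual mean square (sum of squared residuals over
    n - p degrees of freedom, Biacore convention) in RU^2; ``chi2_pct``
    is chi2 / Rmax * 100 with ``high_significance`` true below 5%.
    ``rmax_source`` records whether Rmax came from the full kinetic fit
    ("global_fit") or, for dissociation-only fits without a companion
    full fit, from the largest fitted R0 ("max_R0").
    """

    ka: float
    kd: float
    KD: float
    Rmax: float
    r0: Mapping[str, float]
    chi2: float
    chi2_pct: float
    high_significance: bool
    n_points: int
    n_params: int
    converged: bool
    rmax_source: str = "global_fit"
    message: str = ""
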