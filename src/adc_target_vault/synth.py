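"""Seeded generators for every input the pipeline consumes.

The generators emulate the *structure* of the public annotation and
expression sources the vault is normally populated from — a
UniProt/ENSEMBL-style proteome annotation table, per-predictor
transmembrane topology calls, HPA-style ordinal IHC observations for a
healthy-tissue panel and patient-level cancer summaries, GMT gene-set
collections — plus multi-cycle Biacore-style sensorgrams with reference
flow cells and blank cycles.

A configurable number of "planted" ideal ADC targets is built in by
construction: single-pass transmembrane consensus (>= 5 of 6 predictors
call exactly one segment), zero healthy tissues at Medium-or-High, and a
strict majority of cancer patients at High-or-Medium.  Everything else
("decoys") is drawn from the configured level distributions.  With the
sensorgram noise at zero the simulator output equals the 1:1 Langmuir
model exactly, so the full pipeline is testable against planted truth.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
    INTENSITY_BINS,
    LEVELS,
    QUANTITY_BINS,
    CancerIHCSummary,
    GeneSet,
    HealthyIHCObservation,
    ProteinRecord,
    SensorgramCycle,
    TMPrediction,
    ValidationError,
)
from .spr import model_association, model_dissociation

__all__ = [
    "FixtureConfig",
    "SimSensorgramConfig",
    "gen_proteome",
    "gen_expression",
    "gen_gene_sets",
    "simulate_sensorgram",
    "planted_protein_ids",
    "write_proteome_tsv",
    "write_tm_tsv",
    "write_healthy_tsv",
    "write_cancer_tsv",
    "write_gmt",
    "write_sensorgrams_csv",
    "read_sensorgrams_csv",
    "write_fixture_set",
    "HEALTHY_TISSUES",
    "PREDICTORS",
]

#: The six transmembrane-topology predictors whose calls the consensus
#: filter combines (five individual algorithms plus the consensus
#: predictor itself).
PREDICTORS: Tuple[str, ...] = (
    "TOPCONS",
    "Philius",
    "PolyPhobius",
    "SPOCTOPUS",
    "OCTOPUS",
    "SCAMPI",
)

#: Default healthy-tissue panel (44 tissues, HPA-like).  Only the counts
#: matter to ranking; the names are fixed labels for readability.
HEALTHY_TISSUES: Tuple[str, ...] = (
    "adipose tissue", "adrenal gland", "appendix", "bone marrow", "breast",
    "bronchus", "caudate", "cerebellum", "cerebral cortex", "cervix",
    "colon", "duodenum", "endometrium", "epididymis", "esophagus",
    "fallopian tube", "gallbladder", "heart muscle", "hippocampus",
    "kidney", "liver", "lung", "lymph node", "nasopharynx", "oral mucosa",
    "ovary", "pancreas", "parathyroid gland", "placenta", "prostate",
    "rectum", "salivary gland", "seminal vesicle", "skeletal muscle",
    "skin", "small intestine", "smooth muscle", "spleen", "stomach",
    "testis", "thyroid gland", "tonsil", "urinary bladder", "vagina",
)

_CELL_TYPES: Tuple[str, ...] = ("glandular cells", "stromal cells")

_SUBCELL_VOCAB: Tuple[str, ...] = (
    "Cell membrane", "Cytoplasm", "Nucleus", "Secreted",
    "Endoplasmic reticulum", "Golgi apparatus", "Mitochondrion",
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _check_probs(name: str, probs: Sequence[float], n: int) -> None:
    if len(probs) != n:
        raise ValidationError(f"level_probs[{name}]: expected {n} entries")
    if any(p < 0 for p in probs):
        raise ValidationError(f"level_probs[{name}]: negative probability")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValidationError(f"level_probs[{name}]: must sum to 1 within 1e-9")


def _default_level_probs() -> Dict[str, Tuple[float, ...]]:
    # Order matches LEVELS: (Not detected, Low, Medium, High).
    return {
        # Planted ideal targets carry no healthy Medium/High mass.
        "healthy_planted": (0.7, 0.3, 0.0, 0.0),
        "healthy_decoy": (0.40, 0.30, 0.20, 0.10),
        "cancer_decoy": (0.25, 0.25, 0.25, 0.25),
    }


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of the annotation/expression fixture generators.

    Defaults mirror the study conditions: a 44-tissue healthy IHC panel,
    22 patients per cancer type, six topology predictors, and five
    planted ideal targets among 50 proteins.
    """

    seed: int = 0
    n_proteins: int = 50
    n_healthy_tissues: int = 44
    n_patients: int = 22
    n_planted_targets: int = 5
    predictor_names: Tuple[str, ...] = PREDICTORS
    level_probs: Mapping[str, Tuple[float, ...]] = field(
        default_factory=_default_level_probs
    )
    #: Fraction of decoy proteins given multi-pass or disagreeing
    #: topology calls (the rest pass the single-TM consensus).
    decoy_multi_tm_frac: float = 0.7
    cancer_types: Tuple[str, ...] = ("ovarian cancer",)

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValidationError("n_proteins: must be >= 1")
        if not (0 <= self.n_planted_targets <= self.n_proteins):
            raise ValidationError("n_planted_targets: must be <= n_proteins")
        if len(self.predictor_names) != 6:
            raise ValidationError("predictor_names: exactly 6 required")
        if len(set(self.predictor_names)) != 6:
            raise ValidationError("predictor_names: must be unique")
        if self.n_healthy_tissues < 1 or self.n_healthy_tissues > len(HEALTHY_TISSUES):
            raise ValidationError(
                f"n_healthy_tissues: must be in [1, {len(HEALTHY_TISSUES)}]"
            )
        if self.n_patients < 1:
            raise ValidationError("n_patients: must be >= 1")
        if not (0.0 <= self.decoy_multi_tm_frac <= 1.0):
            raise ValidationError("decoy_multi_tm_frac: must be in [0, 1]")
        for key in ("healthy_planted", "healthy_decoy", "cancer_decoy"):
            if key not in self.level_probs:
                raise ValidationError(f"level_probs: missing stratum {key!r}")
            _check_probs(key, self.level_probs[key], len(LEVELS))
        hp = self.level_probs["healthy_planted"]
        if hp[2] != 0.0 or hp[3] != 0.0:
            raise ValidationError(
                "level_probs[healthy_planted]: Medium/High mass must be 0 "
                "(planted targets have no healthy Medium/High tissue)"
            )

    @property
    def tissues(self) -> Tuple[str, ...]:
        return HEALTHY_TISSUES[: self.n_healthy_tissues]


def planted_protein_ids(cfg: FixtureConfig) -> List[str]:
    """IDs of the planted ideal targets (the first ``n_planted_targets``)."""
    return [f"SYNP{i + 1:05d}" for i in range(cfg.n_planted_targets)]


def gen_proteome(
    cfg: FixtureConfig,
) -> Tuple[List[ProteinRecord], List[TMPrediction]]:
    """Generate the proteome annotation table and per-predictor TM calls.

    Planted targets receive exactly-one-segment calls from at least five
    of the six predictors; a configurable fraction of decoys receive
    multi-pass or disagreeing calls.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = set(range(cfg.n_planted_targets))
    proteins: List[ProteinRecord] = []
    preds: List[TMPrediction] = []
    for i in range(cfg.n_proteins):
        pid = f"SYNP{i + 1:05d}"
        gid = f"ENSG{90000000 + i + 1:011d}"
        sym = f"GS{i + 1:04d}"
        seq_len = int(rng.integers(60, 121))
        seq = "".join(rng.choice(list(_AA20), size=seq_len))
        if i in planted:
            locs = frozenset({"Cell membrane"})
            is_tm = True
        else:
            locs = frozenset(
                rng.choice(_SUBCELL_VOCAB, size=int(rng.integers(1, 3)), replace=False)
            )
            is_tm = bool(rng.random() < 0.5)
        proteins.append(
            ProteinRecord(pid, gid, sym, seq, locs, is_tm)
        )
        preds.extend(_gen_tm_calls(cfg, rng, pid, planted=i in planted))
    return proteins, preds


def _gen_tm_calls(
    cfg: FixtureConfig, rng: np.random.Generator, pid: str, planted: bool
) -> List[TMPrediction]:
    names = cfg.predictor_names
    if planted:
        n_agree = int(rng.integers(5, 7))  # 5 or 6
        agree = set(rng.choice(6, size=n_agree, replace=False))
        counts = [1 if j in agree else int(rng.integers(2, 8)) for j in range(6)]
    elif rng.random() < cfg.decoy_multi_tm_frac:
        counts = [int(c) for c in rng.integers(0, 8, size=6)]
        # Guarantee the consensus filter rejects this decoy.
        while sum(c == 1 for c in counts) >= 5:
            counts[int(rng.integers(0, 6))] = int(rng.choice([0, 2, 3, 7]))
    else:
        # Single-pass decoy: passes the TM filter, competes on expression.
        n_agree = int(rng.integers(5, 7))
        agree = set(rng.choice(6, size=n_agree, replace=False))
        counts = [1 if j in agree else int(rng.integers(2, 8)) for j in range(6)]
    out = []
    for name, c in zip(names, counts):
        segments = ((10, 32),) if c == 1 else None
        out.append(TMPrediction(pid, name, c, segments))
    return out


def gen_expression(
    cfg: FixtureConfig,
    proteins: Sequence[ProteinRecord],
    cancer_type: str = "ovarian cancer",
) -> Tuple[List[HealthyIHCObservation], List[CancerIHCSummary]]:
    """Generate healthy IHC observations and cancer patient summaries.

    Planted targets get zero healthy tissues at Medium/High and a strict
    majority (> 50%) of patients at High-or-Medium; decoys are drawn
    from ``cfg.level_probs``.  Every protein gets one observation per
    healthy tissue per cell type and one summary for ``cancer_type``.
    """
    if cancer_type not in cfg.cancer_types:
        raise ValidationError(
            f"cancer_type: unknown label {cancer_type!r}; "
            f"configured types are {cfg.cancer_types}"
        )
    rng = np.random.default_rng((cfg.seed, zlib.crc32(cancer_type.encode())))
    planted = set(planted_protein_ids(cfg))
    healthy: List[HealthyIHCObservation] = []
    cancer: List[CancerIHCSummary] = []
    for prot in proteins:
        stratum = "healthy_planted" if prot.protein_id in planted else "healthy_decoy"
        probs = np.asarray(cfg.level_probs[stratum], dtype=float)
        for tissue in cfg.tissues:
            for cell_type in _CELL_TYPES:
                lvl = LEVELS[int(rng.choice(len(LEVELS), p=probs))]
                healthy.append(
                    HealthyIHCObservation(prot.protein_id, tissue, cell_type, lvl)
                )
        cancer.append(
            _gen_cancer_summary(cfg, rng, prot.protein_id, cancer_type,
                                planted=prot.protein_id in planted)
        )
    return healthy, cancer


def _gen_cancer_summary(
    cfg: FixtureConfig,
    rng: np.random.Generator,
    pid: str,
    cancer_type: str,
    planted: bool,
) -> CancerIHCSummary:
    n = cfg.n_patients
    if planted:
        # Strict majority High-or-Medium, guaranteed by construction.
        k_hm = int(rng.integers(n // 2 + 1, n + 1))
        n_high = int(rng.binomial(k_hm, 0.7))
        n_medium = k_hm - n_high
        rest = n - k_hm
        n_low = int(rng.binomial(rest, 0.5))
        n_nd = rest - n_low
    else:
        counts = rng.multinomial(n, np.asarray(cfg.level_probs["cancer_decoy"]))
        n_nd, n_low, n_medium, n_high = (int(c) for c in counts)
    intensity = dict(zip(INTENSITY_BINS, map(int, rng.multinomial(
        n, [0.05, 0.2, 0.35, 0.4] if planted else [0.25, 0.25, 0.25, 0.25]))))
    quantity = dict(zip(QUANTITY_BINS, map(int, rng.multinomial(
        n, [0.1, 0.3, 0.6] if planted else [1 / 3, 1 / 3, 1 / 3]))))
    return CancerIHCSummary(
        pid, cancer_type, n_high, n_medium, n_low, n_nd, intensity, quantity
    )


def gen_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    planted_set_genes: Sequence[str],
    query_overlap: int,
    seed: int,
    query_size: int = 100,
) -> Tuple[List[GeneSet], List[str]]:
    """Generate a GMT-style collection with one planted enriched set.

    Returns ``(sets, query)`` where ``query`` is the designated query
    list containing exactly ``query_overlap`` genes of the planted set
    plus random non-member genes; the planted set (named
    ``"PLANTED_SET"``) is enriched in the query by construction.
    """
    universe = list(dict.fromkeys(universe))
    planted_set_genes = list(dict.fromkeys(planted_set_genes))
    if not planted_set_genes:
        raise ValidationError("planted_set_genes: must be non-empty")
    missing = set(planted_set_genes) - set(universe)
    if missing:
        raise ValidationError(f"planted_set_genes: not in universe: {sorted(missing)}")
    if query_overlap > len(planted_set_genes):
        raise ValidationError(
            f"query_overlap: {query_overlap} exceeds planted set size "
            f"{len(planted_set_genes)}"
        )
    if query_size > len(universe):
        raise ValidationError("query_size: exceeds universe size")
    rng = np.random.default_rng(seed)
    sets: List[GeneSet] = [
        GeneSet("PLANTED_SET", "planted enriched set", frozenset(planted_set_genes))
    ]
    for i in range(n_sets - 1):
        size = int(rng.integers(10, min(201, len(universe) + 1)))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(GeneSet(f"RAND_SET_{i + 1:03d}", "random set", frozenset(members)))
    in_planted = list(rng.choice(planted_set_genes, size=query_overlap, replace=False))
    non_members = [g for g in universe if g not in set(planted_set_genes)]
    n_rest = query_size - query_overlap
    if n_rest > len(non_members):
        raise ValidationError("query_size: too large for universe minus planted set")
    rest = list(rng.choice(non_members, size=n_rest, replace=False))
    return sets, sorted(in_planted + rest)


@dataclass(frozen=True)
class SimSensorgramConfig:
    """Configuration of the multi-cycle sensorgram simulator.

    Defaults sit in the study's kinetic regime: association rate
    ~3.7e5 1/(M*s), off-rate 4e-4 1/s, 120 s injections with 600 s
    dissociation, and a five-point two-fold concentration series.
    """

    ka: float = 3.68e5  # 1/(M*s)
    kd: float = 4e-4  # 1/s
    Rmax: float = 100.0  # RU
    concentrations: Tuple[float, ...] = (
        7.8125e-9, 1.5625e-8, 3.125e-8, 6.25e-8, 1.25e-7,
    )
    t_assoc: float = 120.0  # s
    t_dissoc: float = 600.0  # s
    dt: float = 1.0  # s
    noise_sd: float = 0.0  # RU
    drift_slope: float = 0.0  # RU/s
    bulk_shift: float = 0.0  # RU
    seed: int = 0

    def __post_init__(self):
        if self.ka <= 0 or self.kd <= 0 or self.Rmax <= 0:
            raise ValidationError("ka/kd/Rmax: must be > 0")
        conc = tuple(self.concentrations)
        if not conc or any(c <= 0 for c in conc):
            raise ValidationError("concentrations: must be positive")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValidationError("concentrations: must be strictly increasing")
        if self.dt <= 0:
            raise ValidationError("dt: must be > 0")
        if self.t_assoc <= 0 or self.t_dissoc <= 0:
            raise ValidationError("t_assoc/t_dissoc: must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be >= 0")


def _time_grid(duration: float, dt: float) -> np.ndarray:
    # Closed at the phase start: samples at 0, dt, 2dt, ..., <= duration.
    n = int(np.floor(duration / dt + 1e-12))
    return np.arange(n + 1) * dt


def simulate_sensorgram(cfg: SimSensorgramConfig) -> List[SensorgramCycle]:
    """Simulate a multi-cycle kinetic run on active + reference flow cells.

    Emits, in run order, one blank cycle pair (buffer-only injection)
    followed by an active/reference trace pair per concentration, in
    increasing concentration order.  The active trace follows the 1:1
    Langmuir model plus linear baseline drift, a rectangular
    refractive-index bulk shift spanning the association phase, and
    i.i.d. Gaussian noise; reference and blank traces carry the same
    drift and bulk artefacts (noise excepted) but no binding signal.
    """
    rng = np.random.default_rng(cfg.seed)
    ta = _time_grid(cfg.t_assoc, cfg.dt)
    td = _time_grid(cfg.t_dissoc, cfg.dt)

    def artefacts() -> Tuple[np.ndarray, np.ndarray]:
        a = cfg.drift_slope * ta + cfg.bulk_shift
        d = cfg.drift_slope * (cfg.t_assoc + td)
        return a, d

    def noise(n: int) -> np.ndarray:
        if cfg.noise_sd == 0:
            return np.zeros(n)
        return rng.normal(0.0, cfg.noise_sd, size=n)

    cycles: List[SensorgramCycle] = []
    art_a, art_d = artefacts()
    for role in ("active", "reference"):
        cycles.append(SensorgramCycle(
            "BLANK", 0.0, role,
            ta, art_a + noise(ta.size), td, art_d + noise(td.size),
            is_blank=True,
        ))
    for i, conc in enumerate(cfg.concentrations):
        bind_a = model_association(ta, cfg.ka, cfg.kd, conc, cfg.Rmax)
        r0 = float(model_association(cfg.t_assoc, cfg.ka, cfg.kd, conc, cfg.Rmax))
        bind_d = model_dissociation(td, cfg.kd, r0)
        cid = f"C{i + 1}"
        cycles.append(SensorgramCycle(
            cid, conc, "active",
            ta, bind_a + art_a + noise(ta.size), td, bind_d + art_d + noise(td.size),
        ))
        cycles.append(SensorgramCycle(
            cid, conc, "reference",
            ta, art_a + noise(ta.size), td, art_d + noise(td.size),
        ))
    return cycles


# ---------------------------------------------------------------------------
# Plain-text writers / readers for the fixture tables


def write_proteome_tsv(proteins: Sequence[ProteinRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "gene_id", "gene_symbol", "sequence",
                    "subcellular_locations", "is_transmembrane"])
        for p in proteins:
            w.writerow([
                p.protein_id, p.gene_id, p.gene_symbol, p.sequence or "",
                ";".join(sorted(p.subcellular_locations)),
                int(p.is_transmembrane),
            ])


def write_tm_tsv(preds: Sequence[TMPrediction], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "predictor", "n_segments", "segments"])
        for p in preds:
            segs = (";".join(f"{a}-{b}" for a, b in p.segments)
                    if p.segments is not None else "")
            w.writerow([p.protein_id, p.predictor, p.n_segments, segs])


def write_healthy_tsv(obs: Sequence[HealthyIHCObservation], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "tissue", "cell_type", "level"])
        for o in obs:
            w.writerow([o.protein_id, o.tissue, o.cell_type, o.level])


def write_cancer_tsv(summaries: Sequence[CancerIHCSummary], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "cancer_type", "n_high", "n_medium", "n_low",
                    "n_not_detected", "intensity_counts", "quantity_counts"])
        for s in summaries:
            w.writerow([
                s.protein_id, s.cancer_type, s.n_high, s.n_medium, s.n_low,
                s.n_not_detected,
                _enc_counts(s.intensity_counts, INTENSITY_BINS),
                _enc_counts(s.quantity_counts, QUANTITY_BINS),
            ])


def _enc_counts(counts: Optional[Mapping[str, int]], bins: Sequence[str]) -> str:
    if counts is None:
        return ""
    return ";".join(f"{b}={counts.get(b, 0)}" for b in bins)


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


_PHASES = {False: ("assoc", "dissoc"), True: ("blank_assoc", "blank_dissoc")}


def write_sensorgrams_csv(cycles: Sequence[SensorgramCycle], path) -> None:
    """Write cycles as long-format CSV.

    Columns: cycle_id, flow_cell (2=active, 1=reference), role, phase
    (assoc|dissoc|blank_assoc|blank_dissoc), conc_M, t_s, response_RU.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["cycle_id", "flow_cell", "role", "phase",
                    "conc_M", "t_s", "response_RU"])
        for c in cycles:
            fc = 2 if c.role == "active" else 1
            pa, pd_ = _PHASES[c.is_blank]
            for phase, t, r in ((pa, c.t_assoc, c.r_assoc),
                                (pd_, c.t_dissoc, c.r_dissoc)):
                for ti, ri in zip(t, r):
                    w.writerow([c.cycle_id, fc, c.role, phase,
                                repr(float(c.concentration)),
                                repr(float(ti)), repr(float(ri))])


def read_sensorgrams_csv(path) -> List[SensorgramCycle]:
    """Read a sensorgram CSV written by :func:`write_sensorgrams_csv`."""
    rows: Dict[Tuple[str, str], Dict[str, list]] = {}
    conc: Dict[Tuple[str, str], float] = {}
    blank: Dict[Tuple[str, str], bool] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            key = (rec["cycle_id"], rec["role"])
            d = rows.setdefault(key, {"ta": [], "ra": [], "td": [], "rd": []})
            phase = rec["phase"]
            t, r = float(rec["t_s"]), float(rec["response_RU"])
            if phase.endswith("dissoc"):
                d["td"].append(t)
                d["rd"].append(r)
            else:
                d["ta"].append(t)
                d["ra"].append(r)
            conc[key] = float(rec["conc_M"])
            blank[key] = phase.startswith("blank")
    cycles = []
    for key, d in rows.items():
        cid, role = key
        cycles.append(SensorgramCycle(
            cid, conc[key], role, d["ta"], d["ra"], d["td"], d["rd"],
            is_blank=blank[key],
        ))
    return cycles


def write_fixture_set(cfg: FixtureConfig, out_dir, cancer_type: str = "ovarian cancer",
                      ) -> Dict[str, Path]:
    """Generate and write the full annotation/expression fixture set.

    Returns a dict of logical name -> written path (proteome, tm,
    healthy, cancer, gene_sets).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, preds = gen_proteome(cfg)
    healthy, cancer = gen_expression(cfg, proteins, cancer_type)
    symbols = [p.gene_symbol for p in proteins]
    planted = set(planted_protein_ids(cfg))
    planted_syms = [p.gene_symbol for p in proteins if p.protein_id in planted]
    n_extra = max(0, min(15 - len(planted_syms), len(symbols) - len(planted_syms)))
    set_genes = planted_syms + [
        s for s in symbols if s not in set(planted_syms)
    ][:n_extra]
    query_size = len(planted_syms) + min(15, len(symbols) - len(set_genes))
    sets, _query = gen_gene_sets(
        symbols, n_sets=10, planted_set_genes=set_genes,
        query_overlap=len(planted_syms),
        seed=cfg.seed, query_size=query_size,
    )
    paths = {
        "proteome": out / "proteome.tsv",
        "tm": out / "tm_predictions.tsv",
        "healthy": out / "healthy_ihc.tsv",
        "cancer": out / "cancer_ihc.tsv",
        "gene_sets": out / "gene_sets.gmt",
    }
    write_proteome_tsv(proteins, paths["proteome"])
    write_tm_tsv(preds, paths["tm"])
    write_healthy_tsv(healthy, paths["healthy"])
    write_cancer_tsv(cancer, paths["cancer"])
    write_gmt(sets, paths["gene_sets"])
    return paths
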