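"""The ADC Target Vault: an embedded, indexed relational target store.

A single-file SQLite database holding the proteome annotation table,
per-predictor transmembrane calls, healthy-tissue IHC observations and
cancer patient-level IHC summaries, with the query primitives the
ranking stage composes.  Ingestion is typed (every row passes the
domain-record validators), referentially checked, idempotent, and
indexed on protein_id / tissue / cancer_type.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .types import (
    INTENSITY_BINS,
    LEVEL_RANK,
    LEVELS,
    QUANTITY_BINS,
    CancerIHCSummary,
    HealthyIHCObservation,
    ProteinRecord,
    TMPrediction,
    ValidationError,
    normalize_level,
)

__all__ = [
    "Vault",
    "patients_total",
    "ReferentialIntegrityError",
    "ParseError",
    "NotFoundError",
]


class ReferentialIntegrityError(ValueError):
    """A child table row references an unknown protein_id."""


class ParseError(ValueError):
    """A table cell failed to parse; the message carries the line number."""


class NotFoundError(KeyError):
    """A requested protein is not in the store."""


def patients_total(s: CancerIHCSummary) -> int:
    """Total patients behind one cancer IHC summary."""
    return s.n_high + s.n_medium + s.n_low + s.n_not_detected


_SCHEMA = """
CREATE TABLE IF NOT EXISTS proteins (
    protein_id TEXT PRIMARY KEY,
    gene_id TEXT NOT NULL,
    gene_symbol TEXT NOT NULL,
    sequence TEXT,
    subcellular_locations TEXT NOT NULL,
    is_transmembrane INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS tm_predictions (
    protein_id TEXT NOT NULL REFERENCES proteins(protein_id),
    predictor TEXT NOT NULL,
    n_segments INTEGER NOT NULL,
    segments TEXT,
    PRIMARY KEY (protein_id, predictor)
);
CREATE TABLE IF NOT EXISTS healthy_ihc (
    protein_id TEXT NOT NULL REFERENCES proteins(protein_id),
    tissue TEXT NOT NULL,
    cell_type TEXT NOT NULL,
    level TEXT NOT NULL,
    PRIMARY KEY (protein_id, tissue, cell_type)
);
CREATE TABLE IF NOT EXISTS cancer_ihc (
    protein_id TEXT NOT NULL REFERENCES proteins(protein_id),
    cancer_type TEXT NOT NULL,
    n_high INTEGER NOT NULL,
    n_medium INTEGER NOT NULL,
    n_low INTEGER NOT NULL,
    n_not_detected INTEGER NOT NULL,
    intensity_counts TEXT,
    quantity_counts TEXT,
    PRIMARY KEY (protein_id, cancer_type)
);
CREATE INDEX IF NOT EXISTS idx_tm_protein ON tm_predictions(protein_id);
CREATE INDEX IF NOT EXISTS idx_healthy_protein ON healthy_ihc(protein_id);
CREATE INDEX IF NOT EXISTS idx_healthy_tissue ON healthy_ihc(tissue);
CREATE INDEX IF NOT EXISTS idx_cancer_protein ON cancer_ihc(protein_id);
CREATE INDEX IF NOT EXISTS idx_cancer_type ON cancer_ihc(cancer_type);
"""


def _dec_counts(text: Optional[str], bins: Sequence[str]) -> Optional[Dict[str, int]]:
    if not text:
        return None
    out = {}
    for part in text.split(";"):
        key, _, val = part.partition("=")
        out[key] = int(val)
    return out


def _enc_counts(counts, bins: Sequence[str]) -> Optional[str]:
    if counts is None:
        return None
    return ";".join(f"{b}={counts.get(b, 0)}" for b in bins)


class Vault:
    """Handle to an ADC Target Vault store.

    Open with :meth:`create` (new/empty or existing file, or
    ``":memory:"``) and populate either from TSV files via
    :meth:`ingest` or from validated records via
    :meth:`ingest_records`.
    """

    def __init__(self, conn: sqlite3.Connection):
        self._conn = conn
        conn.executescript(_SCHEMA)

    @classmethod
    def create(cls, path=":memory:") -> "Vault":
        conn = sqlite3.connect(str(path))
        conn.execute("PRAGMA foreign_keys = ON")
        return cls(conn)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- ingestion ---------------------------------------------------------

    def ingest(self, proteome_tsv, tm_tsv, healthy_tsv, cancer_tsv) -> "Vault":
        """Ingest the four TSV tables (idempotent; validates every row)."""
        proteins = _read_proteome_tsv(proteome_tsv)
        tms = _read_tm_tsv(tm_tsv)
        healthy = _read_healthy_tsv(healthy_tsv)
        cancer = _read_cancer_tsv(cancer_tsv)
        return self.ingest_records(proteins, tms, healthy, cancer)

    def ingest_records(
        self,
        proteins: Sequence[ProteinRecord],
        tms: Sequence[TMPrediction] = (),
        healthy: Sequence[HealthyIHCObservation] = (),
        cancer: Sequence[CancerIHCSummary] = (),
    ) -> "Vault":
        """Ingest validated domain records (idempotent upsert)."""
        ids = {p.protein_id for p in proteins}
        known = ids | {
            r[0] for r in self._conn.execute("SELECT protein_id FROM proteins")
        }
        for name, rows in (("tm_predictions", tms), ("healthy_ihc", healthy),
                           ("cancer_ihc", cancer)):
            orphans = sorted({r.protein_id for r in rows} - known)
            if orphans:
                raise ReferentialIntegrityError(
                    f"{name}: unknown protein_id values: {orphans}"
                )
        with self._conn:
            self._conn.executemany(
                "INSERT OR REPLACE INTO proteins VALUES (?,?,?,?,?,?)",
                [(p.protein_id, p.gene_id, p.gene_symbol, p.sequence,
                  ";".join(sorted(p.subcellular_locations)),
                  int(p.is_transmembrane)) for p in proteins],
            )
            self._conn.executemany(
                "INSERT OR REPLACE INTO tm_predictions VALUES (?,?,?,?)",
                [(t.protein_id, t.predictor, t.n_segments,
                  json.dumps(t.segments) if t.segments is not None else None)
                 for t in tms],
            )
            self._conn.executemany(
                "INSERT OR REPLACE INTO healthy_ihc VALUES (?,?,?,?)",
                [(o.protein_id, o.tissue, o.cell_type, o.level) for o in healthy],
            )
            self._conn.executemany(
                "INSERT OR REPLACE INTO cancer_ihc VALUES (?,?,?,?,?,?,?,?)",
                [(s.protein_id, s.cancer_type, s.n_high, s.n_medium, s.n_low,
                  s.n_not_detected,
                  _enc_counts(s.intensity_counts, INTENSITY_BINS),
                  _enc_counts(s.quantity_counts, QUANTITY_BINS)) for s in cancer],
            )
        return self

    # -- queries -----------------------------------------------------------

    def protein_ids(self) -> List[str]:
        return [r[0] for r in self._conn.execute(
            "SELECT protein_id FROM proteins ORDER BY protein_id")]

    def protein(self, protein_id: str) -> ProteinRecord:
        row = self._conn.execute(
            "SELECT protein_id, gene_id, gene_symbol, sequence, "
            "subcellular_locations, is_transmembrane FROM proteins "
            "WHERE protein_id = ?", (protein_id,)).fetchone()
        if row is None:
            raise NotFoundError(protein_id)
        locs = frozenset(row[4].split(";")) if row[4] else frozenset()
        return ProteinRecord(row[0], row[1], row[2], row[3], locs, bool(row[5]))

    def proteins(self) -> List[ProteinRecord]:
        return [self.protein(pid) for pid in self.protein_ids()]

    def tm_predictions(self, protein_id: str) -> List[TMPrediction]:
        self._require(protein_id)
        out = []
        for pid, pred, n, segs in self._conn.execute(
                "SELECT protein_id, predictor, n_segments, segments "
                "FROM tm_predictions WHERE protein_id = ? ORDER BY predictor",
                (protein_id,)):
            segments = tuple(map(tuple, json.loads(segs))) if segs else None
            out.append(TMPrediction(pid, pred, n, segments))
        return out

    def healthy_observations(self, protein_id: str) -> List[HealthyIHCObservation]:
        self._require(protein_id)
        return [HealthyIHCObservation(*row) for row in self._conn.execute(
            "SELECT protein_id, tissue, cell_type, level FROM healthy_ihc "
            "WHERE protein_id = ? ORDER BY tissue, cell_type", (protein_id,))]

    def healthy_level_by_tissue(self, protein_id: str) -> Dict[str, str]:
        """Per-tissue expression level: max over the tissue's cell types.

        One entry per tissue with at least one observation; an empty map
        if the protein has no healthy data.
        """
        self._require(protein_id)
        out: Dict[str, str] = {}
        for tissue, level in self._conn.execute(
                "SELECT tissue, level FROM healthy_ihc WHERE protein_id = ?",
                (protein_id,)):
            if tissue not in out or LEVEL_RANK[level] > LEVEL_RANK[out[tissue]]:
                out[tissue] = level
        return out

    def healthy_levels_per_cell_type(self, protein_id: str) -> List[Tuple[str, str, str]]:
        """(tissue, cell_type, level) rows — the no-collapse alternative."""
        return [(o.tissue, o.cell_type, o.level)
                for o in self.healthy_observations(protein_id)]

    def cancer_summary(self, protein_id: str, cancer_type: str
                       ) -> Optional[CancerIHCSummary]:
        row = self._conn.execute(
            "SELECT protein_id, cancer_type, n_high, n_medium, n_low, "
            "n_not_detected, intensity_counts, quantity_counts FROM cancer_ihc "
            "WHERE protein_id = ? AND cancer_type = ?",
            (protein_id, cancer_type)).fetchone()
        if row is None:
            return None
        return CancerIHCSummary(
            row[0], row[1], row[2], row[3], row[4], row[5],
            _dec_counts(row[6], INTENSITY_BINS), _dec_counts(row[7], QUANTITY_BINS),
        )

    def cancer_summaries(self, cancer_type: str) -> List[CancerIHCSummary]:
        rows = self._conn.execute(
            "SELECT protein_id, cancer_type, n_high, n_medium, n_low, "
            "n_not_detected, intensity_counts, quantity_counts FROM cancer_ihc "
            "WHERE cancer_type = ? ORDER BY protein_id", (cancer_type,)).fetchall()
        return [CancerIHCSummary(
            r[0], r[1], r[2], r[3], r[4], r[5],
            _dec_counts(r[6], INTENSITY_BINS), _dec_counts(r[7], QUANTITY_BINS))
            for r in rows]

    def cancer_types(self) -> List[str]:
        return [r[0] for r in self._conn.execute(
            "SELECT DISTINCT cancer_type FROM cancer_ihc ORDER BY cancer_type")]

    def counts(self) -> Dict[str, int]:
        return {tbl: self._conn.execute(f"SELECT COUNT(*) FROM {tbl}").fetchone()[0]
                for tbl in ("proteins", "tm_predictions", "healthy_ihc", "cancer_ihc")}

    def _require(self, protein_id: str) -> None:
        row = self._conn.execute(
            "SELECT 1 FROM proteins WHERE protein_id = ?", (protein_id,)).fetchone()
        if row is None:
            raise NotFoundError(protein_id)

    # -- export ------------------------------------------------------------

    def export_tables(self, out_dir) -> Dict[str, Path]:
        """Write the four tables back out as TSV (round-trips ingest)."""
        from . import synth

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": out / "proteome.tsv",
            "tm": out / "tm_predictions.tsv",
            "healthy": out / "healthy_ihc.tsv",
            "cancer": out / "cancer_ihc.tsv",
        }
        synth.write_proteome_tsv(self.proteins(), paths["proteome"])
        tms = [t for pid in self.protein_ids() for t in self.tm_predictions(pid)]
        synth.write_tm_tsv(tms, paths["tm"])
        healthy = [o for pid in self.protein_ids()
                   for o in self.healthy_observations(pid)]
        synth.write_healthy_tsv(healthy, paths["healthy"])
        cancer = [s for ct in self.cancer_types() for s in self.cancer_summaries(ct)]
        synth.write_cancer_tsv(cancer, paths["cancer"])
        return paths


# ---------------------------------------------------------------------------
# TSV readers (validate row by row; errors carry 1-based line numbers)


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def _read_proteome_tsv(path) -> List[ProteinRecord]:
    df = _read_tsv(path, ["protein_id", "gene_id", "gene_symbol", "sequence",
                          "subcellular_locations", "is_transmembrane"])
    out = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            if row.protein_id in seen:
                raise ValidationError(f"duplicate protein_id {row.protein_id!r}")
            seen.add(row.protein_id)
            locs = frozenset(filter(None, row.subcellular_locations.split(";")))
            out.append(ProteinRecord(
                row.protein_id, row.gene_id, row.gene_symbol,
                row.sequence or None, locs, bool(int(row.is_transmembrane))))
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def _read_tm_tsv(path) -> List[TMPrediction]:
    df = _read_tsv(path, ["protein_id", "predictor", "n_segments", "segments"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segments = None
            if row.segments:
                segments = tuple(
                    tuple(map(int, part.split("-"))) for part in row.segments.split(";")
                )
            out.append(TMPrediction(row.protein_id, row.predictor,
                                    int(row.n_segments), segments))
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def _read_healthy_tsv(path) -> List[HealthyIHCObservation]:
    df = _read_tsv(path, ["protein_id", "tissue", "cell_type", "level"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(HealthyIHCObservation(
                row.protein_id, row.tissue, row.cell_type, normalize_level(row.level)))
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def _read_cancer_tsv(path) -> List[CancerIHCSummary]:
    df = _read_tsv(path, ["protein_id", "cancer_type", "n_high", "n_medium",
                          "n_low", "n_not_detected", "intensity_counts",
                          "quantity_counts"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(CancerIHCSummary(
                row.protein_id, row.cancer_type, int(row.n_high),
                int(row.n_medium), int(row.n_low), int(row.n_not_detected),
                _dec_counts(row.intensity_counts, INTENSITY_BINS),
                _dec_counts(row.quantity_counts, QUANTITY_BINS)))
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out
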