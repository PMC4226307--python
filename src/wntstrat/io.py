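"""Readers and writers for the tabular formats every pipeline stage touches.

Expression data travel as genes-by-samples matrices (plain TSV or GCT 1.2),
gene sets as GMT with an optional two-column direction companion, and
clinical/survival annotation as a flat CSV/TSV keyed by sample id.

Gene identity is the upper-cased symbol string: symbols are upper-cased on
ingest so that panels from different platforms (DASL, Affymetrix, Agilent)
match by symbol.  Missing expression values may be encoded as an empty cell
or ``NA`` and are propagated as NaN, never imputed at I/O time.  Survival
times are in months; units are metadata and are never rescaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATHOLOGICAL_SUBTYPES = ("HR+", "HER2+", "TN")
INTRINSIC_SUBTYPES = ("luminal", "basal", "HER2e", "normal-like")
GRADES = (1, 2, 3)
NODE_STATUSES = ("negative", "positive")
WNT_CALLS = ("Wnt+", "Wnt-")
ENDPOINTS = ("OS", "RFS", "MFS")
METASTASIS_SITES = ("lung", "brain", "bone", "other")

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}

CLINICAL_COLUMNS = (
    "pathological_subtype",
    "intrinsic_subtype",
    "grade",
    "node_status",
    "wnt_call",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes-by-samples intensity table with cohort identity and scale flag.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene symbols with unique sample-id
        columns.  Values may contain NaN (missing) but never +/-inf.
    cohort_id
        Free-form cohort/platform label.
    scale
        ``"log2"`` or ``"linear"``.
    """

    data: pd.DataFrame
    cohort_id: str = ""
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        dup_genes = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene ids: {dup_genes}")
        dup_samples = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample ids: {dup_samples}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise TypeError("expression values must be numeric")
        if values.size and np.isinf(values).any():
            raise ValueError("expression values must be finite where not missing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Copy carrying over cohort metadata, optionally changing the scale flag."""
        return ExpressionMatrix(data=data, cohort_id=self.cohort_id,
                                scale=self.scale if scale is None else scale)


@dataclass(frozen=True)
class GeneSet:
    """Named gene list, optionally signed (+1 induced / -1 inhibited)."""

    name: str
    members: tuple[str, ...]
    description: str = "na"
    direction: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            dups = sorted({g for g in self.members if list(self.members).count(g) > 1})
            raise ValueError(f"gene set {self.name!r} has duplicate members: {dups}")
        if self.direction is not None:
            extra = sorted(set(self.direction) - set(self.members))
            if extra:
                raise ValueError(
                    f"direction genes not in set {self.name!r}: {extra}")
            bad = {g: s for g, s in self.direction.items() if s not in (1, -1)}
            if bad:
                raise ValueError(f"direction signs must be +1/-1, got {bad}")

    @property
    def induced(self) -> tuple[str, ...]:
        if self.direction is None:
            return ()
        return tuple(g for g in self.members if self.direction.get(g) == 1)

    @property
    def inhibited(self) -> tuple[str, ...]:
        if self.direction is None:
            return ()
        return tuple(g for g in self.members if self.direction.get(g) == -1)

    def flipped(self) -> "GeneSet":
        """Same set with every direction sign negated."""
        if self.direction is None:
            return self
        return replace(self, direction={g: -s for g, s in self.direction.items()})


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation restricted to fixed category sets.

    Index is the unique sample id; columns are ``pathological_subtype``
    (HR+/HER2+/TN), ``intrinsic_subtype`` (luminal/basal/HER2e/normal-like),
    ``grade`` (1/2/3), ``node_status`` (negative/positive) and ``wnt_call``
    (Wnt+/Wnt-).  Unknown categories are NA.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample ids in clinical table: {dup}")
        for col in CLINICAL_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = pd.NA
        allowed = {
            "pathological_subtype": set(PATHOLOGICAL_SUBTYPES),
            "intrinsic_subtype": set(INTRINSIC_SUBTYPES),
            "grade": set(GRADES),
            "node_status": set(NODE_STATUSES),
            "wnt_call": set(WNT_CALLS),
        }
        for col, ok in allowed.items():
            vals = set(self.data[col].dropna().unique())
            bad = vals - ok
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(map(str, bad))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class SurvivalRecord:
    """One follow-up record: time in months, event flag, endpoint, optional site.

    The metastasis site is defined only for MFS events; censored records and
    OS/RFS records carry ``site=None``.
    """

    sample_id: str
    time: float
    event: int
    endpoint: str
    site: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative follow-up time {self.time} for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}")
        if self.site is not None:
            if self.endpoint != "MFS" or self.event != 1:
                raise ValueError(
                    f"site is defined only for MFS events (sample {self.sample_id})")
            if self.site not in METASTASIS_SITES:
                raise ValueError(f"unknown metastasis site {self.site!r}")


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of survival records."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "endpoint": [r.endpoint for r in records],
            "site": [r.site for r in records],
        }
    )


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """String cells -> float, mapping missing tokens to NaN; error names the cell."""
    out = {}
    for col in df.columns:
        raw = df[col].astype(str).str.strip()
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & ~raw.isin(_MISSING_TOKENS)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value {raw[bad].iloc[0]!r} at gene {gene!r}, sample {col!r}")
        out[col] = numeric
    return pd.DataFrame(out, index=df.index)


def _check_gene_index(index: pd.Index) -> pd.Index:
    index = index.astype(str).str.strip().str.upper()
    dup = index[index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene ids: {dup}")
    return index


def read_expression(path: str | Path, format: str = "tsv", scale: str = "log2",
                    cohort_id: str | None = None) -> ExpressionMatrix:
    """Read a genes-by-samples matrix from TSV (first column = symbol) or GCT 1.2.

    Row and column ordering is preserved from the file.  Duplicate gene or
    sample ids and non-numeric cells are hard errors naming the offender.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version not in ("#1.2",):
                raise ValueError(f"unsupported GCT version line {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ValueError("malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
        if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
            raise ValueError(
                f"GCT header declares {n_genes}x{n_samples} but body is "
                f"{body.shape[0]}x{body.shape[1] - 2}")
        df = body.set_index(body.columns[0]).drop(columns=body.columns[1])
    else:
        raise ValueError(f"unknown expression format {format!r}")

    dup_samples = pd.Index(df.columns)[pd.Index(df.columns).duplicated()].unique().tolist()
    if dup_samples:
        raise ValueError(f"duplicate sample ids: {dup_samples}")
    df.index = _check_gene_index(df.index)
    df = _coerce_numeric(df)
    return ExpressionMatrix(df, cohort_id=cohort_id or path.stem, scale=scale)


def write_expression(X: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        X.data.to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{X.n_genes}\t{X.n_samples}\n")
            out = X.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# gene-set I/O (GMT + optional direction companion)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, direction_path: str | Path | None = None) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line.

    A companion two-column file (gene, +1/-1) attaches direction signs to every
    set; a direction gene absent from a set is an error.  Companion files are
    therefore intended for single-signature GMTs.
    """
    direction = read_gene_directions(direction_path) if direction_path else None
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, desc = parts[0], parts[1]
            members = tuple(g.strip().upper() for g in parts[2:] if g.strip())
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, members=members, description=desc,
                                direction=dict(direction) if direction else None))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_gene_directions(path: str | Path) -> dict[str, int]:
    """Two-column TSV gene -> sign; accepts +1/-1/+/-."""
    signs = {"+1": 1, "1": 1, "+": 1, "-1": -1, "-": -1}
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in signs:
                raise ValueError(f"{path}:{lineno}: expected 'GENE <+1|-1>', got {line!r}")
            out[parts[0].strip().upper()] = signs[parts[1]]
    return out


# ---------------------------------------------------------------------------
# clinical + survival I/O
# ---------------------------------------------------------------------------

_CATEGORY_MAPS = {
    "pathological_subtype": {s: s for s in PATHOLOGICAL_SUBTYPES},
    "intrinsic_subtype": {s: s for s in INTRINSIC_SUBTYPES},
    "node_status": {s: s for s in NODE_STATUSES},
    "wnt_call": {s: s for s in WNT_CALLS},
}


def read_clinical_survival(path: str | Path) -> tuple[ClinicalTable, list[SurvivalRecord]]:
    """Read a long-format CSV/TSV of clinical annotation and survival records.

    One row per sample x endpoint; clinical columns are taken from the first
    occurrence of each sample.  Unknown category spellings are mapped to NA
    and the total count is logged.  Negative times and event flags outside
    {0, 1} are hard errors.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("clinical/survival file must have a 'sample_id' column")
    df = df.replace(dict.fromkeys(_MISSING_TOKENS, pd.NA))

    unknown = 0
    for col, mapping in _CATEGORY_MAPS.items():
        if col not in df.columns:
            continue
        raw = df[col]
        mapped = raw.map(mapping)
        unknown += int((raw.notna() & mapped.isna()).sum())
        df[col] = mapped
    if "grade" in df.columns:
        grade = pd.to_numeric(df["grade"], errors="coerce")
        ok = grade.isin(GRADES)
        unknown += int((df["grade"].notna() & ~ok).sum())
        df["grade"] = grade.where(ok).astype("Int64")
    if unknown:
        logger.warning("%s: %d unrecognized clinical values mapped to NA", path, unknown)

    clin = df.drop_duplicates(subset="sample_id", keep="first").set_index("sample_id")
    clin = clin.reindex(columns=list(CLINICAL_COLUMNS))
    clinical = ClinicalTable(clin)

    records: list[SurvivalRecord] = []
    if "time" in df.columns and "event" in df.columns:
        for _, row in df.iterrows():
            if pd.isna(row.get("time")) or pd.isna(row.get("event")):
                continue
            time = float(row["time"])
            try:
                event_raw = float(row["event"])
            except ValueError as exc:
                raise ValueError(f"event must be 0 or 1, got {row['event']!r}") from exc
            if event_raw not in (0.0, 1.0):
                raise ValueError(f"event must be 0 or 1, got {row['event']!r}")
            event = int(event_raw)
            site = row.get("site")
            records.append(SurvivalRecord(
                sample_id=str(row["sample_id"]), time=time, event=event,
                endpoint=str(row.get("endpoint", "OS")),
                site=None if pd.isna(site) else str(site)))
    return clinical, records


def write_clinical_survival(clinical: ClinicalTable, records: Sequence[SurvivalRecord],
                            path: str | Path) -> None:
    """Inverse of :func:`read_clinical_survival` (long format, one row per record).

    Samples without any survival record are written as a clinical-only row.
    """
    surv = records_to_frame(records)
    clin = clinical.data.reset_index(names="sample_id")
    seen = set(surv["sample_id"])
    rows = surv.merge(clin, on="sample_id", how="left")
    only_clin = clin[~clin["sample_id"].isin(seen)]
    out = pd.concat([rows, only_clin], ignore_index=True)
    cols = ["sample_id", *CLINICAL_COLUMNS, "time", "event", "endpoint", "site"]
    out = out.reindex(columns=cols)
    out["event"] = out["event"].astype("Int64")
    out.to_csv(path, sep="\t", index=False)
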