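"""Containers and file formats.

Every external artifact crosses this module: expression matrices
(genes x samples TSV), cell-line count matrices with sample metadata,
gene-set collections (GMT), clinical tables, probe maps, study-effect
tables and serialized signature models. Readers reject malformed input
with errors naming the file, line and field; every reader/writer pair
round-trips value-identically.

Tabular dialect: TSV, UTF-8, decimal point ``.``, no thousands separators.
Column contracts
----------------
expression TSV   first column ``gene_id``, header row = sample ids
clinical TSV     ``sample_id  time  event`` + free covariate columns;
                 time in months, event 1=event/0=censored
study TSV        ``study  hr  ci_low  ci_high  n``
probe map TSV    ``probe_id  gene_id``
sample meta TSV  ``sample_id  line  condition  replicate``,
                 condition in {hypoxia, normoxia}
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

CONDITIONS = ("hypoxia", "normoxia")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with provenance flags.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``scale`` is ``"linear"`` or ``"log2"``; ``centred`` records whether
    each gene has been median-centred across the cohort.
    """

    values: pd.DataFrame
    scale: str = "linear"
    centred: bool = False
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise SchemaError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise SchemaError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        if self.scale == "log2" and not np.isfinite(self.values.to_numpy()).all():
            raise SchemaError("log2 matrix contains non-finite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CountMatrix:
    """Integer counts with per-sample (line, condition, replicate) metadata."""

    counts: pd.DataFrame
    meta: pd.DataFrame  # indexed by sample id: line, condition, replicate

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise SchemaError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise SchemaError("counts must be non-negative")
        missing = self.counts.columns.difference(self.meta.index)
        if len(missing):
            raise SchemaError(f"samples missing from metadata: {list(missing)[:3]}")
        self.meta = self.meta.loc[self.counts.columns]
        bad = set(self.meta["condition"]) - set(CONDITIONS)
        if bad:
            raise SchemaError(f"unknown condition labels {sorted(bad)}")

    @property
    def lines(self) -> list[str]:
        return sorted(self.meta["line"].unique())


@dataclass
class ProbeMap:
    """Many-probes-to-one-gene mapping; every probe maps to exactly one gene."""

    mapping: pd.Series  # index probe_id -> gene_id

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            dup = self.mapping.index[self.mapping.index.duplicated()][0]
            raise SchemaError(f"probe {dup!r} mapped more than once")

    def genes_for(self, probes: pd.Index) -> pd.Series:
        missing = probes.difference(self.mapping.index)
        if len(missing):
            raise SchemaError(f"probe {missing[0]!r} absent from probe map")
        return self.mapping.loc[probes]


@dataclass
class ClinicalTable:
    """Per-sample follow-up: time (months), event flag and covariates."""

    data: pd.DataFrame  # indexed by sample_id; columns time, event, covariates

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise SchemaError(f"clinical table missing column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        n0 = len(df)
        df = df.dropna(subset=["time", "event"])
        if len(df) < n0:
            logger.info("dropped %d samples with missing time/event", n0 - len(df))
        if (df["time"] < 0).any():
            bad = df.index[df["time"] < 0][0]
            raise SchemaError(f"negative follow-up time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])][0]
            raise SchemaError(f"event flag not in {{0,1}} for sample {bad!r}")
        self.data = df

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise SchemaError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class StudyEffectTable:
    """Published per-study hazard ratios with CI bounds and sample sizes."""

    data: pd.DataFrame  # columns study, hr, ci_low, ci_high, n

    def __post_init__(self) -> None:
        df = self.data
        for col in ("study", "hr", "ci_low", "ci_high", "n"):
            if col not in df.columns:
                raise SchemaError(f"study table missing column {col!r}")
        for _, row in df.iterrows():
            if not (0 < row.ci_low <= row.hr <= row.ci_high):
                raise SchemaError(
                    f"study {row.study!r}: CI ordering violated "
                    f"(need 0 < ci_low <= hr <= ci_high)"
                )
            if row.n < 1:
                raise SchemaError(f"study {row.study!r}: n must be >= 1")


# ---------------------------------------------------------------------------
# expression TSV


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_tsv(path, scale: str = "linear", centred: bool = False,
                        platform_tag: str = "") -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ParseError(f"{path}: duplicate sample id {sid!r} in header")
        seen.add(sid)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ParseError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene row {dup!r}")
    return ExpressionMatrix(df, scale=scale, centred=centred, platform_tag=platform_tag)


# ---------------------------------------------------------------------------
# counts + sample metadata


def write_counts_tsv(cm: CountMatrix, counts_path, meta_path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    meta = cm.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_counts_tsv(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    for col in ("line", "condition", "replicate"):
        if col not in meta.columns:
            raise SchemaError(f"{meta_path}: missing column {col!r}")
    return CountMatrix(counts, meta)


# ---------------------------------------------------------------------------
# GMT


def write_gmt(c: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in c.sets.items():
            desc = c.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected name, description and at "
                    f"least one member, got {len(fields)} field(s)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# clinical / probe map / study effects


def write_clinical_tsv(t: ClinicalTable, path) -> None:
    out = t.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_clinical_tsv(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_probe_map_tsv(pm: ProbeMap, path) -> None:
    out = pm.mapping.rename("gene_id").to_frame()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_probe_map_tsv(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "gene_id" not in df.columns:
        raise SchemaError(f"{path}: missing column 'gene_id'")
    return ProbeMap(df["gene_id"])


def write_study_effects_tsv(t: StudyEffectTable, path) -> None:
    t.data.to_csv(path, sep="\t", index=False)


def read_study_effects_tsv(path) -> StudyEffectTable:
    df = pd.read_csv(path, sep="\t")
    return StudyEffectTable(df)


# ---------------------------------------------------------------------------
# model serialization (versioned structured text; gene order is contractual)


def save_model(model, path) -> None:
    """Serialize an NscModel as versioned JSON text."""
    payload = {"format_version": MODEL_FORMAT_VERSION, **model.to_dict()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path):
    from .nsc import NscModel  # local import to avoid a cycle

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.pop("format_version", None)
    if version != MODEL_FORMAT_VERSION:
        raise SchemaError(
            f"{path}: model format version {version!r}, "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    return NscModel.from_dict(payload)
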