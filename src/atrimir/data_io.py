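"""Input/output and core containers for the miRNA/mRNA aging pipeline.

Count matrices, sample metadata, miRNA target tables and gene-set (GMT)
collections are all plain tab-separated text.  Counts are normalised only by
raw library size (column totals); abundance is reported as log2
counts-per-million (logCPM) with an edgeR-style prior count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("SR40", "SR50", "SR60", "SR70")
#: age band (inclusive) permitted per group when ages are auto-assigned
GROUP_AGE_BANDS = {
    "SR40": (38, 42),
    "SR50": (48, 52),
    "SR60": (58, 62),
    "SR70": (68, 72),
}


class DataValidationError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class CountMatrix:
    """Integer read counts, features x samples.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with one column per sample id;
        entries are non-negative integers.
    feature_kind
        Either ``"miRNA"`` or ``"gene"``.
    """

    counts: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("miRNA", "gene"):
            raise DataValidationError(
                f"feature_kind must be 'miRNA' or 'gene', got {self.feature_kind!r}"
            )
        if self.counts.shape[0] == 0:
            raise DataValidationError("no features in count matrix")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            raise DataValidationError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataValidationError("non-numeric entries in count matrix")
        if np.any(values < 0):
            f, s = np.argwhere(values < 0)[0]
            raise DataValidationError(
                f"negative count at feature {self.counts.index[f]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            f, s = np.argwhere(values != np.round(values))[0]
            raise DataValidationError(
                f"non-integer count at feature {self.counts.index[f]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


@dataclass
class ExpressionMatrix:
    """Real-valued expression (logCPM), features x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise DataValidationError("non-finite values in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TargetDB:
    """miRNA -> predicted/validated target gene sets.

    Backed by a deduplicated record table with columns
    ``mirna, gene, source, evidence``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mirna", "gene", "source", "evidence"}
        missing = required - set(self.records.columns)
        if missing:
            raise DataValidationError(f"target table missing columns: {sorted(missing)}")
        bad = set(self.records["evidence"]) - {"predicted", "validated"}
        if bad:
            raise DataValidationError(f"unknown evidence levels: {sorted(bad)}")
        n0 = len(self.records)
        self.records = self.records.drop_duplicates(subset=["mirna", "gene"]).reset_index(
            drop=True
        )
        if len(self.records) < n0:
            logger.info("target table: dropped %d duplicate pairs", n0 - len(self.records))

    def targets_of(self, mirna: str, validated_only: bool = False) -> set[str]:
        rec = self.records
        if validated_only:
            rec = rec[rec["evidence"] == "validated"]
        return set(rec.loc[rec["mirna"] == mirna, "gene"])

    def __contains__(self, pair: tuple[str, str]) -> bool:
        mirna, gene = pair
        return bool(
            ((self.records["mirna"] == mirna) & (self.records["gene"] == gene)).any()
        )

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.records["mirna"], self.records["gene"]))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT), e.g. pathways, with unique ids and non-empty members."""

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            if not members:
                raise DataValidationError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_count_matrix(path, feature_kind: str) -> CountMatrix:
    """Read a TSV count matrix (first column feature ids, header sample ids).

    Malformed content (negative, non-integer, duplicate ids, empty file) raises
    :class:`DataValidationError` rather than being coerced.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"no features in {path}") from None
    if df.shape[0] == 0:
        raise DataValidationError(f"no features in {path}")
    parsed = {}
    for col in df.columns:
        try:
            parsed[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise DataValidationError(f"non-numeric count in column {col!r}: {exc}") from None
    return CountMatrix(pd.DataFrame(parsed, index=df.index), feature_kind=feature_kind)


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature")


def read_sample_table(path) -> pd.DataFrame:
    """Read sample metadata (columns sample_id, group, age, sex) and validate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "sex": str})
    return validate_sample_table(df)


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"sample table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise DataValidationError("duplicate sample ids in sample table")
    bad_groups = set(df["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise DataValidationError(f"unknown groups: {sorted(bad_groups)}")
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_sex:
        raise DataValidationError(f"unknown sex values: {sorted(bad_sex)}")
    return df.reset_index(drop=True)


def library_sizes(cm: CountMatrix) -> np.ndarray:
    """Per-sample library sizes = raw column totals.

    A zero-total sample cannot be normalised and is an error.
    """
    sizes = cm.values.sum(axis=0)
    if np.any(sizes == 0):
        bad = [s for s, t in zip(cm.sample_ids, sizes) if t == 0]
        raise DataValidationError(f"zero library size for samples: {bad}")
    return sizes


def log_cpm(
    cm: CountMatrix,
    prior_count: float = 0.5,
    lib_sizes: np.ndarray | None = None,
    norm_factors: np.ndarray | None = None,
) -> ExpressionMatrix:
    """log2 counts-per-million with a pseudo-count.

    value[f, s] = log2( (count[f, s] + prior) / (libsize[s] + 2*prior) * 1e6 )

    The pseudo-count (edgeR-style convention, default 0.5) keeps zeros finite;
    ``prior_count = 0`` is only valid when every count is positive.
    ``norm_factors`` is a hook for plug-in between-sample normalisation factors
    multiplying the library sizes; the default is 1.0 (raw totals only).
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    lib = library_sizes(cm) if lib_sizes is None else np.asarray(lib_sizes, dtype=float)
    if norm_factors is not None:
        lib = lib * np.asarray(norm_factors, dtype=float)
    counts = cm.values.astype(float)
    if prior_count == 0 and np.any(counts == 0):
        raise DataValidationError("prior_count=0 with zero counts: log of zero")
    vals = np.log2((counts + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)
    )


def read_target_db(path) -> TargetDB:
    """Read a miRNA->gene target table (columns mirna, gene, source, evidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TargetDB(df)


def write_target_db(db: TargetDB, path) -> None:
    db.records.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``id<TAB>description<TAB>gene...``."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            set_id, desc = fields[0], fields[1]
            if set_id in sets:
                raise DataValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = {g for g in fields[2:] if g}
            sets[set_id] = members
            descriptions[set_id] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in gsc.sets:
            members = "\t".join(sorted(gsc.sets[set_id]))
            fh.write(f"{set_id}\t{gsc.descriptions.get(set_id, '')}\t{members}\n")


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a result table as TSV; round-trips losslessly at 10 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
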