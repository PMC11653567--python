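"""Tabular I/O and validation for the cross-expression pipeline.

All files are plain TSV (tab-separated, header row, '.' decimal).  The three
inputs are a transcript x sample count matrix, a sample metadata table
describing the reciprocal-cross design (sex, dam line, sire line, cross,
replicate), and a gene annotation table giving each transcript's chromosome
class (autosome / X / Y) plus an optional two-column gene -> GO term map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError, ValidationError

SEXES = ("female", "male")
CHROM_CLASSES = ("autosome", "X", "Y")

_GO_RE = re.compile(r"^GO:\d{7}$")

SAMPLE_COLUMNS = ("sample_id", "sex", "dam", "sire", "cross", "replicate")


@dataclass
class CountMatrix:
    """Integer transcript x sample count matrix.

    Invariants: unique gene and sample ids, dimensions matching the id
    lists, and non-negative integral counts.  Raw counts only -- never
    normalized values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicated gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicated sample id {dup!r}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.floor(counts)))
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count {counts[i, j]!r} at gene "
                    f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray | list[str]) -> "CountMatrix":
        """Row subset preserving order; `keep` is a boolean mask or id list."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([g in wanted for g in self.gene_ids])
        return CountMatrix(
            [g for g, m in zip(self.gene_ids, mask) if m],
            list(self.sample_ids),
            self.counts[mask],
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        """Column subset in the order given."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def read_counts(path) -> CountMatrix:
    """Read a count TSV: first column gene ids, header row of sample ids.

    Row and column order of the file are preserved.  A non-numeric,
    negative or fractional cell raises :class:`ParseError` naming the
    offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(vals)
    bad |= vals != np.floor(vals)
    bad |= vals < 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"invalid count {df.iat[i, j]!r} at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}: "
            "counts must be non-negative integers"
        )
    try:
        return CountMatrix(gene_ids, sample_ids, vals.astype(np.int64))
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_counts(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t")


def read_samples(path, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Read and validate the sample metadata table.

    Required columns: sample_id, sex, dam, sire, cross, replicate.  The
    genotype label is derived dam-first (dam 'A' x sire 'B' -> 'AB'), so
    the two reciprocal heterozygotes get distinct labels and a sample is
    homozygous iff dam == sire.  When `counts` is given the table must
    match its samples one-to-one; rows are reordered to the matrix column
    order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_samples(df, counts)


def validate_samples(df: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    df = df.copy()
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"sample table missing columns: {missing_cols}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicated sample id {dup!r}")
    bad_sex = sorted(set(df["sex"]) - set(SEXES))
    if bad_sex:
        raise ParseError(f"unknown sex token(s) {bad_sex}; expected one of {SEXES}")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive integers")
    df["genotype"] = df["dam"].astype(str) + df["sire"].astype(str)
    df["homozygous"] = df["dam"] == df["sire"]
    if "excluded" not in df.columns:
        df["excluded"] = False
    else:
        df["excluded"] = df["excluded"].astype(str).str.lower().isin(("true", "1", "yes"))
    if "exclude_reason" not in df.columns:
        df["exclude_reason"] = ""
    df["exclude_reason"] = df["exclude_reason"].fillna("")
    if counts is not None:
        table_ids = set(df["sample_id"])
        matrix_ids = set(counts.sample_ids)
        only_matrix = sorted(matrix_ids - table_ids)
        only_table = sorted(table_ids - matrix_ids)
        if only_matrix or only_table:
            raise DesignError(
                f"sample mismatch between counts and metadata; in counts only: "
                f"{only_matrix}; in metadata only: {only_table}"
            )
        df = df.set_index("sample_id").loc[counts.sample_ids].reset_index()
    return df


def validate_design(samples: pd.DataFrame) -> None:
    """Require the full 4-genotype x 2-sex grid within every cross.

    For a cross between lines L1 and L2 the four genotypes are the two
    homozygotes and the two reciprocal heterozygotes.  Any missing
    (cross, genotype, sex) cell raises :class:`DesignError` listing it.
    """
    missing: list[tuple] = []
    for cross, sub in samples.groupby("cross"):
        lines = sorted(set(sub["dam"]) | set(sub["sire"]))
        if len(lines) != 2:
            raise DesignError(
                f"cross {cross!r} involves lines {lines}; expected exactly two"
            )
        l1, l2 = lines
        expected = [l1 + l1, l2 + l2, l1 + l2, l2 + l1]
        have = {(g, s) for g, s in zip(sub["genotype"], sub["sex"])}
        for g in expected:
            for s in SEXES:
                if (g, s) not in have:
                    missing.append((cross, g, s))
    if missing:
        raise DesignError(f"design cells missing (cross, genotype, sex): {missing}")


def reciprocal_pairs(samples: pd.DataFrame) -> dict[str, str]:
    """Map each heterozygote genotype label to its reciprocal partner."""
    out: dict[str, str] = {}
    for g in samples.loc[~samples["homozygous"], "genotype"].unique():
        out[g] = g[::-1] if len(g) == 2 else "".join(reversed(list(g)))
    # genotypes with multi-character line labels: rebuild from dam/sire
    for _, row in samples.loc[~samples["homozygous"]].iterrows():
        out[row["genotype"]] = str(row["sire"]) + str(row["dam"])
    return out


def read_genes(path, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Read the gene annotation table (gene_id, chrom_class).

    When `counts` is given, every transcript in the matrix must be
    annotated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "chrom_class"):
        if col not in df.columns:
            raise ParseError(f"gene table missing column {col!r}")
    bad = sorted(set(df["chrom_class"]) - set(CHROM_CLASSES))
    if bad:
        raise ParseError(f"unknown chrom_class token(s) {bad}; expected one of {CHROM_CLASSES}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicated gene id {dup!r} in gene table")
    if counts is not None:
        missing = sorted(set(counts.gene_ids) - set(df["gene_id"]))
        if missing:
            raise ValidationError(
                f"{len(missing)} matrix genes missing from gene table, e.g. {missing[:5]}"
            )
    return df.reset_index(drop=True)


def read_go_map(path) -> pd.DataFrame:
    """Read a two-column gene -> GO term map (one pair per line).

    Duplicated pairs are dropped; malformed GO identifiers ('GO:' + seven
    digits) raise :class:`ParseError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ParseError("GO map must have two columns: gene_id, go_id")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "go_id"]
    bad = [t for t in df["go_id"] if not _GO_RE.match(str(t))]
    if bad:
        raise ParseError(f"malformed GO identifier(s), e.g. {bad[:3]}")
    return df.drop_duplicates().reset_index(drop=True)


def write_go_map(go_map: pd.DataFrame, path) -> None:
    go_map.to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-transcript results table losslessly.

    Column order is preserved and floats are written with 17 significant
    digits so that re-reading reproduces every value bit-identically.
    """
    results.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    # round_trip parsing: the default fast parser can be off by 1 ulp
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
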