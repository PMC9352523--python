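"""Core data containers and file I/O.

The pipeline works with four kinds of observations:

* a genus-level 16S count table (samples x genera, integer reads),
* a rooted phylogeny over the genera (Newick, branch lengths),
* per-sample clinical metadata (group, timepoint, age, sex, comorbidity
  flags, prior antibiotic exposure),
* analyte response panels (cytokine / degranulation measurements per
  stimulus and cell type) together with per-analyte detection limits.

All tabular formats are plain UTF-8 text with "." as the decimal mark:
count tables are TSV with a leading ``sample_id`` column and one column
per genus; metadata and panels are CSV.  Missing analyte values are an
explicit empty cell / NaN, never a silent zero.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

GROUPS = ("CAP", "control")
TIMEPOINTS = ("admission", "month", "none")
SEXES = ("male", "female")
COMORBIDITY_FLAGS = (
    "copd",
    "cardiovascular",
    "diabetes",
    "malignancy",
    "immunosuppressed",
    "gastrointestinal",
    "renal",
)
METADATA_COLUMNS = (
    ("group", "timepoint", "age", "sex") + COMORBIDITY_FLAGS + ("prior_antibiotics",)
)

STIMULI = ("LPS", "Kpneumoniae", "none")
CELL_TYPES = ("monocyte", "PMN", "serum")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    taxon_ids : list of str
        Unique genus identifiers, one per column.
    counts : ndarray of int, shape (n_samples, n_taxa)
        Read counts; every row must contain at least one read.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(self.sample_ids) < 1 or len(self.taxon_ids) < 2:
            raise ValidationError("need at least 1 sample and 2 taxa")
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.taxon_ids, "taxon id")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.round(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int, atol=0, rtol=0):
                raise ValidationError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("negative counts are not allowed")
        if (self.counts.sum(axis=1) < 1).any():
            bad = [s for s, d in zip(self.sample_ids, self.counts.sum(axis=1)) if d < 1]
            raise ValidationError(f"samples with zero total reads: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalized proportions (each row sums to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(sample_ids), list(self.taxon_ids), self.counts[idx])


@dataclass
class PhyloTree:
    """Rooted phylogeny over the genera, with non-negative branch lengths.

    Wraps a :class:`skbio.TreeNode`.  Missing branch lengths are set to 0
    (with a logged warning); internal node labels are ignored.
    """

    tree: TreeNode

    def __post_init__(self) -> None:
        n_missing = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValidationError(f"negative branch length at node {node.name!r}")
        if self.tree.length is None:
            self.tree.length = 0.0
        if n_missing:
            logger.warning("%d branches had no length; set to 0", n_missing)
        leaves = self.leaf_names()
        _check_unique(leaves, "leaf label")
        if len(leaves) < 2:
            raise ValidationError("tree must have at least 2 leaves")

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.tree.traverse(include_self=False))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates.

    Stored as a DataFrame indexed by sample id with columns ``group``
    (CAP/control), ``timepoint`` (admission/month/none), ``age`` (years),
    ``sex``, seven boolean comorbidity flags and ``prior_antibiotics``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        _check_unique(df.index, "sample id")
        for col, levels in (("group", GROUPS), ("timepoint", TIMEPOINTS), ("sex", SEXES)):
            if df[col].isna().any():
                raise ValidationError(f"missing values in required column {col!r}")
            bad = set(df[col]) - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
        if df["age"].isna().any() or (df["age"] <= 0).any():
            raise ValidationError("age must be positive for every sample")
        for col in COMORBIDITY_FLAGS + ("prior_antibiotics",):
            self.data[col] = df[col].astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def select_samples(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


@dataclass
class AnalyteLimits:
    """Per-analyte lower detection limit and upper limit of quantification."""

    limits: pd.DataFrame  # index analyte, columns lower/upper

    def __post_init__(self) -> None:
        df = self.limits
        for col in ("lower", "upper"):
            if col not in df.columns:
                raise ValidationError(f"limits missing column {col!r}")
        if (df["lower"] <= 0).any() or (df["upper"] <= df["lower"]).any():
            raise ValidationError("limits must satisfy 0 < lower < upper")
        _check_unique(df.index, "analyte")


@dataclass
class ResponsePanel:
    """Samples x analytes panel of continuous immune-response measurements.

    ``values`` is a DataFrame indexed by sample id with one column per
    analyte; NaN marks a missing measurement.  ``analytes`` carries the
    per-analyte stimulus and cell type annotations.
    """

    values: pd.DataFrame
    analytes: pd.DataFrame  # index analyte, columns stimulus / cell_type

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample id")
        _check_unique(self.values.columns, "analyte")
        missing = [a for a in self.values.columns if a not in self.analytes.index]
        if missing:
            raise ValidationError(f"analytes without annotation: {missing}")
        for col, levels in (("stimulus", STIMULI), ("cell_type", CELL_TYPES)):
            if col not in self.analytes.columns:
                raise ValidationError(f"analyte annotation missing column {col!r}")
            bad = set(self.analytes[col]) - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("analyte values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    def select_samples(self, sample_ids) -> "ResponsePanel":
        return ResponsePanel(self.values.loc[list(sample_ids)].copy(), self.analytes)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path) -> CountTable:
    """Read a genus-level count table from TSV.

    The first row is the taxon header (first cell ``sample_id``), each
    subsequent row is one sample.  Non-integer cells and duplicate ids
    are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse count table {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ValidationError(f"count table {path} has no taxon columns (line 1)")
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in count table {path}: {exc}") from exc
    if not np.isfinite(counts).all():
        raise ValidationError(f"non-finite or missing cell in count table {path}")
    if not np.array_equal(counts, np.round(counts)):
        raise ValidationError(f"non-integer count in {path}")
    return CountTable(list(df.index), list(df.columns), counts.astype(np.int64))


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")


def read_tree_newick(path) -> PhyloTree:
    """Read a rooted tree with branch lengths from a Newick file."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValidationError(f"cannot parse Newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def write_tree_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def read_metadata(path) -> SampleMetadata:
    """Read per-sample clinical metadata from CSV (index column sample_id)."""
    df = pd.read_csv(path, index_col=0)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.rename_axis("sample_id").to_csv(path)


def read_response_panel(values_path, analytes_path) -> ResponsePanel:
    """Read panel values and analyte annotations from two CSV files."""
    values = pd.read_csv(values_path, index_col=0)
    analytes = pd.read_csv(analytes_path, index_col=0)
    return ResponsePanel(values, analytes)


def write_response_panel(panel: ResponsePanel, values_path, analytes_path) -> None:
    panel.values.rename_axis("sample_id").to_csv(values_path)
    panel.analytes.rename_axis("analyte").to_csv(analytes_path)


def read_analyte_limits(path) -> AnalyteLimits:
    return AnalyteLimits(pd.read_csv(path, index_col=0))


def write_analyte_limits(limits: AnalyteLimits, path) -> None:
    limits.limits.rename_axis("analyte").to_csv(path)


def apply_detection_limits(panel: ResponsePanel, limits: AnalyteLimits) -> ResponsePanel:
    """Censor panel values at the assay detection limits.

    Values above the upper limit of quantification are set to the upper
    limit; values below the lower detection limit are set to half the
    lower limit.  Missing values stay missing.  Idempotent because
    ``lower/2 < lower <= upper``.
    """
    missing = [a for a in panel.analyte_names if a not in limits.limits.index]
    if missing:
        raise ValidationError(f"no detection limits configured for: {missing}")
    values = panel.values.copy()
    n_censored = 0
    for analyte in panel.analyte_names:
        lo = limits.limits.loc[analyte, "lower"]
        hi = limits.limits.loc[analyte, "upper"]
        col = values[analyte]
        above = col > hi
        below = col < lo
        n_censored += int(above.sum() + below.sum())
        values.loc[above, analyte] = hi
        values.loc[below, analyte] = lo / 2.0
    logger.info("detection-limit censoring affected %d cells", n_censored)
    return ResponsePanel(values, panel.analytes)
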