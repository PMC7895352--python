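"""Count matrices, TE feature taxonomy, and the sample design.

The pipeline starts from a TEcount-style count matrix: one row per feature
(genes named by gene id, transposable elements named ``name:family:class``),
one column per sample, integer counts.  The sample design table assigns each
sample a cell type (e.g. THP1 or MDM), an irradiation dose in Gy, and a
biological replicate / donor id; the experimental *group* is the cell type
crossed with the dose (``THP1_5`` = THP1 cells, 5 Gy), which is the single
factor all downstream testing is run across.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "FeatureAnnotation",
    "SampleDesign",
    "ValidationError",
    "read_counts",
    "write_counts",
    "annotate_features",
    "build_design",
    "read_design",
    "group_label",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def group_label(cell_type: str, dose_Gy: float) -> str:
    """Group label: cell type crossed with dose, e.g. ``THP1_5``.

    Integral doses are printed without a decimal point so that the common
    0/5 Gy design yields the labels ``THP1_0``, ``THP1_5``, ``MDM_0``,
    ``MDM_5``.
    """
    dose = float(dose_Gy)
    dose_str = str(int(dose)) if dose == int(dose) else ("%g" % dose)
    return f"{cell_type}_{dose_str}"


@dataclass(frozen=True)
class FeatureAnnotation:
    """Classification of one feature id as a gene or a TE.

    A feature id is a TE iff it consists of exactly three colon-separated
    non-empty tokens (``name:family:class``, the TEcount convention); any
    other id is a gene.  The parse is loss-free: ``":".join((te_name,
    te_family, te_class))`` reproduces the id.
    """

    feature_id: str
    kind: str  # "gene" | "TE"
    te_name: str | None = None
    te_family: str | None = None
    te_class: str | None = None


@dataclass
class CountMatrix:
    """Feature x sample matrix of non-negative integer counts.

    ``counts`` is a pandas DataFrame indexed by feature id with sample ids
    as columns.  Validation happens at construction: ids unique, counts
    integral and non-negative, at least two samples, every library size
    (column sum) positive.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if df.shape[1] < 2:
            raise ValidationError("need at least 2 samples")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(values.astype(float))):
            raise ValidationError("counts contain non-finite values")
        frac, _ = np.modf(values.astype(float))
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise ValidationError(
                f"non-integer count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        zero = df.sum(axis=0) == 0
        if zero.any():
            raise ValidationError(
                f"zero library size for sample(s): {list(df.columns[zero])}"
            )
        self.counts = df.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)].copy())


def read_counts(path, delimiter: str = "\t") -> CountMatrix:
    """Read a delimited count table (first column = feature ids, header = samples)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # a text cell anywhere is a validation problem, not a parse crash
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric count cell: {exc}") from exc
    return CountMatrix(numeric)


def write_counts(cm: CountMatrix, path, delimiter: str = "\t") -> None:
    """Write the canonical form: feature column named 'feature', tab-delimited."""
    out = cm.counts.copy()
    out.index.name = "feature"
    out.to_csv(path, sep=delimiter)


def canonical_counts_text(cm: CountMatrix, delimiter: str = "\t") -> str:
    buf = io.StringIO()
    write_counts(cm, buf, delimiter=delimiter)
    return buf.getvalue()


def annotate_features(feature_ids) -> list[FeatureAnnotation]:
    """Classify every feature id; total (no errors).

    ``AluY:Alu:SINE`` -> TE(name=AluY, family=Alu, class=SINE); anything not
    matching the exact three-token shape (including ids with 2 or 4 colons or
    empty tokens) is a gene.
    """
    out = []
    for fid in feature_ids:
        parts = str(fid).split(":")
        if len(parts) == 3 and all(parts):
            out.append(
                FeatureAnnotation(
                    feature_id=str(fid),
                    kind="TE",
                    te_name=parts[0],
                    te_family=parts[1],
                    te_class=parts[2],
                )
            )
        else:
            out.append(FeatureAnnotation(feature_id=str(fid), kind="gene"))
    return out


@dataclass
class SampleDesign:
    """Per-sample cell type, dose and replicate id, with derived group labels.

    Invariants: sample ids unique; every group has >= 2 samples; >= 2 groups.
    Construction is order-independent: rows are sorted by sample id.
    """

    table: pd.DataFrame  # index: sample_id; columns: cell_type, dose_Gy, replicate_id, group
    groups: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"cell_type", "dose_Gy", "replicate_id"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"design missing column(s): {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id in design: {dup!r}")
        if (t["dose_Gy"].astype(float) < 0).any():
            raise ValidationError("dose_Gy must be non-negative")
        t = t.sort_index()
        t["group"] = [
            group_label(ct, d) for ct, d in zip(t["cell_type"], t["dose_Gy"])
        ]
        self.table = t
        groups: dict[str, list[str]] = {}
        for sid, g in t["group"].items():
            groups.setdefault(g, []).append(sid)
        if len(groups) < 2:
            raise ValidationError("need at least 2 groups")
        small = {g: s for g, s in groups.items() if len(s) < 2}
        if small:
            raise ValidationError(
                f"group(s) with a single sample (CV and ANOVA need >= 2): {sorted(small)}"
            )
        self.groups = groups

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, sample_id: str) -> str:
        return self.table.loc[sample_id, "group"]

    def check_against(self, cm: CountMatrix) -> None:
        """Require the design and count matrix to cover exactly the same samples."""
        a, b = set(self.sample_ids), set(cm.sample_ids)
        if a != b:
            raise ValidationError(
                "design/counts sample mismatch; only in design: "
                f"{sorted(a - b)}; only in counts: {sorted(b - a)}"
            )

    def group_sizes(self) -> pd.Series:
        return pd.Series({g: len(s) for g, s in self.groups.items()}).sort_index()


def build_design(table: pd.DataFrame) -> SampleDesign:
    """Build a SampleDesign from a DataFrame with a sample_id column (or index)."""
    t = table.copy()
    if "sample_id" in t.columns:
        t = t.set_index("sample_id")
    t.index = t.index.astype(str)
    return SampleDesign(t)


def read_design(path, delimiter: str = "\t") -> SampleDesign:
    return build_design(pd.read_csv(path, sep=delimiter))
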