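"""Normalization and differential-expression calls for two-group time-course arrays.

The processing chain mirrors classic two-color/one-color microarray practice:
raw intensities are floored at 0.01, log2-transformed, each chip (column) is
shifted so its 75th percentile sits at zero, and — for the mRNA platform —
each gene (row) is centered on its median across samples.  Differential
expression at a time point is a per-entity Welch t-test of injured vs sham
replicates with Benjamini–Hochberg adjustment, and an entity "passes" when
|log2 fold change| >= log2(fc_threshold) and adjusted p <= alpha (both
thresholds inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "normalize",
    "differential_expression",
    "classify_entities",
]

_META_COLS = ("sample_id", "group", "time_h", "replicate")
_GROUPS = ("sham", "injured")


@dataclass
class ExpressionMatrix:
    """Entities x samples of (log2) intensities plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by entity id, one column per sample id.
    samples
        DataFrame with columns ``sample_id``, ``group`` ("sham"/"injured"),
        ``time_h`` (hours, float), ``replicate`` (int).
    entity_class
        Platform tag: ``"mRNA"`` or ``"miR"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    entity_class: str = "mRNA"

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        self.samples = self.samples.reset_index(drop=True)
        bad = set(self.samples["group"]) - set(_GROUPS)
        if bad:
            raise ValueError(f"unknown groups in metadata: {sorted(bad)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate entity ids in expression matrix")
        if set(self.values.columns) != set(self.samples["sample_id"]):
            raise ValueError("expression columns and sample metadata disagree")
        # keep column order aligned with the metadata table
        self.values = self.values[list(self.samples["sample_id"])]

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.samples["time_h"].unique())

    def columns_for(self, group: str, time_h: float) -> list[str]:
        m = (self.samples["group"] == group) & (self.samples["time_h"] == time_h)
        return list(self.samples.loc[m, "sample_id"])

    def to_tsv(self, values_path, samples_path) -> None:
        self.values.rename_axis("entity_id").to_csv(values_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, values_path, samples_path, entity_class: str = "mRNA") -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="entity_id", comment="#")
        samples = pd.read_csv(samples_path, sep="\t", comment="#")
        return cls(values=values, samples=samples, entity_class=entity_class)


def normalize(
    raw: ExpressionMatrix,
    per_gene_median: bool = True,
    floor: float = 0.01,
    chip_quantile: float = 0.75,
) -> ExpressionMatrix:
    """Floor, log2, per-chip 75th-percentile scaling, optional per-gene median centering.

    ``per_gene_median`` is the mRNA-platform mode; the miRNA platform skips the
    per-gene step.  The column quantile uses linear interpolation (NumPy's
    default, R type 7).
    """
    if raw.values.size == 0:
        raise ValueError("cannot normalize an empty expression matrix")
    vals = raw.values.to_numpy(dtype=float)
    if not np.isfinite(vals).all() and np.isnan(vals).any():
        raise ValueError("raw matrix contains missing values")
    vals = np.log2(np.clip(vals, floor, None))
    vals = vals - np.quantile(vals, chip_quantile, axis=0, keepdims=True)
    if per_gene_median:
        vals = vals - np.median(vals, axis=1, keepdims=True)
    out = pd.DataFrame(vals, index=raw.values.index, columns=raw.values.columns)
    return ExpressionMatrix(values=out, samples=raw.samples.copy(), entity_class=raw.entity_class)


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p per row; zero-variance rows resolved by the means."""
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    return np.nan_to_num(p, nan=1.0)


def differential_expression(
    matrix: ExpressionMatrix,
    time_h: float,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Injured-vs-sham DE calls at one time point.

    Returns a DataFrame with columns ``entity_id, class, time_h, log2fc,
    p_raw, p_adj, passes``; ``class`` is the platform tag ("mRNA" or "miR")
    until :func:`classify_entities` refines it.  BH adjustment is applied
    across all entities of the platform at this time point.
    """
    inj_cols = matrix.columns_for("injured", time_h)
    sham_cols = matrix.columns_for("sham", time_h)
    for name, cols in (("injured", inj_cols), ("sham", sham_cols)):
        if len(cols) < 2:
            raise ValueError(
                f"group '{name}' has {len(cols)} samples at time {time_h} h; need >= 2"
            )
    inj = matrix.values[inj_cols].to_numpy(dtype=float)
    sham = matrix.values[sham_cols].to_numpy(dtype=float)
    log2fc = inj.mean(axis=1) - sham.mean(axis=1)
    p_raw = _welch_p(inj, sham)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    lfc_cut = np.log2(fc_threshold)
    passes = (np.abs(log2fc) >= lfc_cut) & (p_adj <= alpha)
    return pd.DataFrame(
        {
            "entity_id": matrix.entity_ids,
            "class": matrix.entity_class,
            "time_h": float(time_h),
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "passes": passes,
        }
    )


def classify_entities(de_results: pd.DataFrame, tf_ids) -> pd.DataFrame:
    """Split mRNA-platform entities into TFs and plain mRNAs by an id list.

    miRNA-platform entities keep class ``miR``.  An id present on both
    platforms is a namespace collision and is rejected.
    """
    tf_ids = set(tf_ids)
    out = de_results.copy()
    mir_ids = set(out.loc[out["class"] == "miR", "entity_id"])
    mrna_ids = set(out.loc[out["class"] != "miR", "entity_id"])
    clash = mir_ids & mrna_ids
    if clash:
        raise ValueError(f"entity ids present on both platforms: {sorted(clash)[:5]}")
    is_mrna = out["class"] != "miR"
    out.loc[is_mrna, "class"] = np.where(
        out.loc[is_mrna, "entity_id"].isin(tf_ids), "TF", "mRNA"
    )
    return out
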