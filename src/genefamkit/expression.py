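"""FPKM expression processing and 2^-ddCT qPCR quantification.

The RNA-seq side filters never-expressed genes, log2-transforms FPKM for
heatmaps, formalises tissue-preferential grouping with the tau specificity
index (0 = uniform, 1 = single-tissue), and calls stress responses from
log2 fold changes against the control column.  The qPCR side implements
the Livak 2^-ddCT method with a replicate-level two-sample Student's
t-test on dCT values (significance at p < 0.05).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TISSUES = ["leaf", "root", "stem", "grain", "spike"]
STRESS_CONDITIONS = ["drought_1h", "drought_6h", "heat_1h", "heat_6h"]
CONTROL = "control"


def filter_unexpressed(matrix: pd.DataFrame, min_fpkm: float = 0.5) -> pd.DataFrame:
    """Drop genes whose FPKM is below ``min_fpkm`` in every column (a gene
    reaching ``min_fpkm`` exactly in any column is retained)."""
    keep = (matrix >= min_fpkm).any(axis=1)
    removed = matrix.index[~keep].tolist()
    if removed:
        logger.info("filtered %d never-expressed genes: %s", len(removed), removed)
    result = matrix.loc[keep]
    if result.empty:
        logger.warning("no genes remain after expression filtering")
    return result


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Heatmap transform: value -> log2(value + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(matrix + pseudocount)


def tau_index(values: np.ndarray) -> float:
    """Tissue-specificity index tau = sum(1 - x_i / x_max) / (n - 1)."""
    x = np.asarray(values, dtype=float)
    if x.max() <= 0:
        return float("nan")
    return float((1.0 - x / x.max()).sum() / (x.size - 1))


def tissue_specificity(
    matrix: pd.DataFrame,
    tissues: list[str] | None = None,
    tau_threshold: float = 0.8,
    min_peak_fpkm: float = 1.0,
    ubiquitous_tau: float = 0.2,
) -> pd.DataFrame:
    """Per-gene tau and expression class over the tissue columns.

    tau is computed on log2(x + 1); class is ``tissue_specific:<tissue>``
    (tau >= threshold and peak FPKM >= min_peak_fpkm), ``ubiquitous``
    (tau <= ubiquitous_tau and every tissue >= min_peak_fpkm), ``silent``
    (all-zero) or ``mixed``.
    """
    tissues = tissues or [t for t in TISSUES if t in matrix.columns]
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissue columns")
    sub = matrix[tissues]
    logged = np.log2(sub + 1.0)
    rows = []
    for gene, raw in sub.iterrows():
        if (raw == 0).all():
            rows.append((gene, float("nan"), "silent", ""))
            continue
        tau = tau_index(logged.loc[gene].to_numpy())
        peak_tissue = raw.idxmax()
        if tau >= tau_threshold and raw.max() >= min_peak_fpkm:
            cls = f"tissue_specific:{peak_tissue}"
        elif tau <= ubiquitous_tau and (raw >= min_peak_fpkm).all():
            cls = "ubiquitous"
        else:
            cls = "mixed"
        rows.append((gene, tau, cls, peak_tissue))
    return pd.DataFrame(rows, columns=["gene_id", "tau", "class", "peak_tissue"]).set_index(
        "gene_id"
    )


def stress_response_calls(
    matrix: pd.DataFrame,
    control: str = CONTROL,
    conditions: list[str] | None = None,
    log2fc_threshold: float = 1.0,
    min_fpkm: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Up/down/ns calls per gene and stress condition.

    log2FC = log2((stress + pseudocount) / (control + pseudocount)); genes
    below ``min_fpkm`` in both columns are ns regardless of the ratio.
    """
    if control not in matrix.columns:
        raise ValueError(f"missing control column {control!r}")
    conditions = conditions or [c for c in STRESS_CONDITIONS if c in matrix.columns]
    rows = []
    for gene, row in matrix.iterrows():
        ctrl = row[control]
        for cond in conditions:
            val = row[cond]
            lfc = float(np.log2((val + pseudocount) / (ctrl + pseudocount)))
            if val < min_fpkm and ctrl < min_fpkm:
                call = "ns"
            elif lfc >= log2fc_threshold:
                call = "up"
            elif lfc <= -log2fc_threshold:
                call = "down"
            else:
                call = "ns"
            rows.append((gene, cond, lfc, call))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "log2fc", "call"])


def heatmap_long_format(matrix: pd.DataFrame, classes: pd.DataFrame | None = None,
                        pseudocount: float = 1.0) -> pd.DataFrame:
    """Long-format (gene, sample, log2 value[, class]) heatmap export,
    rows ordered by class then gene id."""
    logged = log2_transform(matrix, pseudocount)
    long = logged.reset_index(names="gene_id").melt(
        id_vars="gene_id", var_name="sample", value_name="log2_value"
    )
    if classes is not None:
        long = long.merge(classes["class"], left_on="gene_id", right_index=True, how="left")
        long = long.sort_values(["class", "gene_id", "sample"], kind="stable")
    return long.reset_index(drop=True)


def _ttest_dct(treat: np.ndarray, ctrl: np.ndarray, equal_var: bool = True) -> float:
    if np.var(treat) == 0 and np.var(ctrl) == 0:
        return 1.0 if np.mean(treat) == np.mean(ctrl) else 0.0
    with warnings.catch_warnings():
        # scipy warns about near-identical replicate values; expected for
        # low-noise qPCR fixtures
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(treat, ctrl, equal_var=equal_var).pvalue)


def ddct(
    qpcr: pd.DataFrame,
    control_treatment: str = CONTROL,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCT method with replicate t-tests.

    ``qpcr`` columns: gene, treatment, replicate, ct_target, ct_reference.
    Per replicate dCT = ct_target - ct_reference; ddCT = mean dCT(treat) -
    mean dCT(control); relative expression = 2^-ddCT; p-value from a
    two-sided two-sample Student's t-test on replicate dCT values.
    """
    required = {"gene", "treatment", "replicate", "ct_target", "ct_reference"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if qpcr["ct_reference"].isna().any() or qpcr["ct_target"].isna().any():
        raise ValueError("missing Ct values in qPCR table")
    table = qpcr.assign(dct=qpcr["ct_target"] - qpcr["ct_reference"])
    if control_treatment not in set(table["treatment"]):
        raise ValueError(f"control treatment {control_treatment!r} not present")
    rows = []
    for gene, gene_tab in table.groupby("gene", sort=True):
        ctrl = gene_tab.loc[gene_tab["treatment"] == control_treatment, "dct"].to_numpy()
        if ctrl.size < 2:
            raise ValueError(f"gene {gene}: need >=2 control replicates")
        for treatment, sub in gene_tab.groupby("treatment", sort=True):
            if treatment == control_treatment:
                continue
            vals = sub["dct"].to_numpy()
            if vals.size < 2:
                raise ValueError(f"gene {gene}, {treatment}: need >=2 replicates")
            ddct_val = float(vals.mean() - ctrl.mean())
            p = _ttest_dct(vals, ctrl, equal_var=equal_var)
            rows.append(
                (gene, treatment, ddct_val, float(2.0 ** (-ddct_val)), p, p < alpha)
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "treatment", "ddct", "relative_expression", "p_value",
                 "significant"],
    )
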