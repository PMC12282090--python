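"""Gene-level differential expression and iModulon coverage of DEGs.

Coverage asks: of the genes called significantly up- (or down-)
regulated between two sample groups, what fraction belongs to at least
one iModulon member set? A decomposition that explains the regulatory
structure of the data should capture most of them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, SampleContrast
from .ica import ComponentModel

DEFAULT_DELTA_CUTOFF = 2.0  # log2-TPM units
DEFAULT_FDR_CUTOFF = 0.1


def gene_differential(
    X: ExpressionMatrix,
    contrast: SampleContrast,
    delta_cutoff: float = DEFAULT_DELTA_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    method: str = "welch",
    replicate_pairs: list[tuple] | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression on the log-TPM scale.

    ``delta_log_tpm`` is group_b mean − group_a mean. With the default
    ``method="welch"``, p-values come from a Welch two-sample t-test with
    unequal variances; ``method="replicate_null"`` instead fits a
    log-normal null to absolute replicate-pair differences per gene
    (the same construction as the activity-level test) — supplied as an
    alternative interpretation since only the thresholds, not the test,
    are fixed by convention. BH correction across genes; a gene is
    significant when q < fdr_cutoff and |delta| > delta_cutoff, with
    ``direction`` +1/−1 by the sign of delta (0 when not significant).
    """
    ga, gb = sorted(contrast.group_a), sorted(contrast.group_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each contrast group needs at least 2 samples")
    va = X.values[ga].to_numpy()
    vb = X.values[gb].to_numpy()
    delta = vb.mean(axis=1) - va.mean(axis=1)

    if method == "welch":
        _, pvals = stats.ttest_ind(vb, va, axis=1, equal_var=False)
        pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance genes
    elif method == "replicate_null":
        if not replicate_pairs:
            raise ValueError("replicate_null method requires replicate_pairs")
        diffs = np.column_stack(
            [
                np.abs(X.values[s1].to_numpy() - X.values[s2].to_numpy())
                for s1, s2 in replicate_pairs
            ]
        )
        logd = np.log(np.maximum(diffs, 1e-6))
        mu = logd.mean(axis=1)
        sigma = np.maximum(logd.std(axis=1, ddof=1), 1e-6)
        z = (np.log(np.maximum(np.abs(delta), 1e-6)) - mu) / sigma
        pvals = stats.norm.sf(z)
    else:
        raise ValueError(f"unknown method {method!r}")

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    significant = (qvals < fdr_cutoff) & (np.abs(delta) > delta_cutoff)
    direction = np.where(significant, np.sign(delta).astype(int), 0)
    out = pd.DataFrame(
        {
            "delta_log_tpm": delta,
            "pvalue": pvals,
            "qvalue": qvals,
            "direction": direction,
        },
        index=X.gene_ids,
    )
    out.attrs["contrast"] = contrast.label
    return out


def coverage(deg: pd.DataFrame, model: ComponentModel) -> dict:
    """Fraction of significant genes captured by iModulon member sets.

    Returns ``{"up": fraction, "down": fraction}``; a direction with no
    significant genes is reported as NaN (coverage undefined).
    """
    union = model.member_union()
    out = {}
    for label, sign in (("up", 1), ("down", -1)):
        sig = set(deg.index[deg["direction"] == sign])
        out[label] = float("nan") if not sig else len(sig & union) / len(sig)
    return out
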