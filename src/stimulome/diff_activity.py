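"""Differential iModulon activity with an empirical log-normal null.

The test works at the component level: for each component, the absolute
activity differences between paired biological replicates form an
empirical null; a log-normal distribution is fitted to them (mean/SD of
the log). For a two-group contrast, the group-mean activity difference
ΔA is compared against that component's null to get a p-value (the
log-normal survival function at |ΔA|), p-values across components are
Benjamini–Hochberg corrected to q-values, and a component is flagged as
highly active when |ΔA| exceeds a cutoff (default 5 activity units) at
q below an FDR cutoff (default 0.1).

Because the null is built purely from replicate noise, any systematic
condition-level variation counts as signal; the test is conservative for
group means (averaging shrinks noise below the single-pair scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import SampleContrast
from .ica import ActivityMatrix

DEFAULT_DELTA_CUTOFF = 5.0
DEFAULT_FDR_CUTOFF = 0.1
#: Floor for near-zero replicate differences before taking logs, in
#: activity units. The log of a near-zero difference is unboundedly
#: negative and a single such pair can inflate the fitted sigma_ln enough
#: to mask real shifts; 0.05 bounds that tail while staying two orders of
#: magnitude below any meaningful activity difference (the flag cutoff
#: is 5).
EPSILON = 0.05
SIGMA_FLOOR = 1e-6


@dataclass
class ReplicateNull:
    """Per-component log-normal null of replicate activity differences.

    ``params`` has one row per component with columns ``mu_ln`` (location
    of log|d|), ``sigma_ln`` (scale of log|d|) and ``n_pairs``. Obtained
    from :func:`fit_replicate_null` or ``DifferentialActivity.fit``.
    """

    params: pd.DataFrame
    epsilon: float = EPSILON

    def survival(self, component: str, abs_delta: float) -> float:
        """P(|replicate difference| > |ΔA|) under the fitted log-normal."""
        row = self.params.loc[component]
        x = max(abs_delta, self.epsilon)
        z = (np.log(x) - row["mu_ln"]) / row["sigma_ln"]
        return float(stats.norm.sf(z))

    def test_contrast(
        self,
        A: ActivityMatrix,
        contrast: SampleContrast,
        delta_cutoff: float = DEFAULT_DELTA_CUTOFF,
        fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    ) -> pd.DataFrame:
        return test_contrast(A, contrast, self, delta_cutoff, fdr_cutoff)


def fit_replicate_null(
    A: ActivityMatrix,
    replicate_pairs: list[tuple],
    epsilon: float = EPSILON,
) -> ReplicateNull:
    """Fit the log-normal replicate null for every component.

    For each component, collect d = |A(s1) − A(s2)| over all supplied
    biological replicate pairs (pooled across conditions), floor values
    below ``epsilon`` at ``epsilon``, and fit by the mean and SD of
    log d. A degenerate SD of 0 is floored at 1e-6 with a warning.
    """
    if len(replicate_pairs) < 2:
        raise ValueError("need at least 2 replicate pairs")
    samples = set(A.sample_ids)
    for pair in replicate_pairs:
        for s in pair:
            if s not in samples:
                raise ValueError(f"replicate pair references missing sample {s!r}")
    vals = A.values
    diffs = np.column_stack(
        [np.abs(vals[s1].to_numpy() - vals[s2].to_numpy()) for s1, s2 in replicate_pairs]
    )
    logd = np.log(np.maximum(diffs, epsilon))
    mu = logd.mean(axis=1)
    sigma = logd.std(axis=1, ddof=1)
    if (sigma <= 0).any():
        warnings.warn("degenerate replicate null: sigma_ln floored at 1e-6")
        sigma = np.maximum(sigma, SIGMA_FLOOR)
    params = pd.DataFrame(
        {"mu_ln": mu, "sigma_ln": sigma, "n_pairs": len(replicate_pairs)},
        index=vals.index,
    )
    return ReplicateNull(params=params, epsilon=epsilon)


def test_contrast(
    A: ActivityMatrix,
    contrast: SampleContrast,
    null: ReplicateNull,
    delta_cutoff: float = DEFAULT_DELTA_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> pd.DataFrame:
    """Differential activity of every component for one contrast.

    ΔA is group_b mean − group_a mean. p is the null survival function
    at |ΔA|; q is Benjamini–Hochberg across the components of this
    contrast; ``high_activity`` requires |ΔA| > delta_cutoff and
    q < fdr_cutoff.
    """
    for grp, name in ((contrast.group_a, "a"), (contrast.group_b, "b")):
        missing = set(grp) - set(A.sample_ids)
        if missing:
            raise ValueError(f"contrast group {name} samples missing: {sorted(missing)}")
    missing_null = set(A.component_names) - set(null.params.index)
    if missing_null:
        raise ValueError(f"components missing from null: {sorted(missing_null)}")
    mean_a = A.values[list(contrast.group_a)].mean(axis=1)
    mean_b = A.values[list(contrast.group_b)].mean(axis=1)
    delta = mean_b - mean_a
    pvals = np.array(
        [null.survival(c, abs(delta[c])) for c in A.component_names]
    )
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "delta_A": delta,
            "pvalue": pvals,
            "qvalue": qvals,
            "high_activity": (delta.abs() > delta_cutoff) & (qvals < fdr_cutoff),
        },
        index=A.component_names,
    )
    out.attrs["contrast"] = contrast.label
    return out


def select_high_density_components(results: list[pd.DataFrame]) -> frozenset:
    """Components flagged highly active in at least one contrast.

    The union over a batch of contrast results identifies the putatively
    condition-specific (e.g. high-cell-density-specific) components.
    """
    if not results:
        raise ValueError("no contrast results supplied")
    out = frozenset()
    for res in results:
        out |= frozenset(res.index[res["high_activity"]])
    return out


class DifferentialActivity:
    """Model wrapper: activities + replicate pairing → fitted null.

    ``DifferentialActivity(A, pairs).fit()`` returns a
    :class:`ReplicateNull` results object with a ``test_contrast``
    method.
    """

    def __init__(
        self,
        A: ActivityMatrix,
        replicate_pairs: list[tuple],
        epsilon: float = EPSILON,
    ):
        self.A = A
        self.replicate_pairs = list(replicate_pairs)
        self.epsilon = epsilon

    def fit(self) -> ReplicateNull:
        return fit_replicate_null(self.A, self.replicate_pairs, self.epsilon)
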