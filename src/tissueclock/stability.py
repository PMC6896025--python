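"""Bootstrap elastic-net stability selection.

The FDR-passing probe submatrix is resampled with replacement at the
sample level; an elastic-net regression of age on the probes is fitted
per resample and the nonzero-coefficient support recorded. Probes whose
selection frequency exceeds the threshold (strictly more than 95% of
bootstraps by default, 500 bootstraps in the reference protocol) form
the marker set of a tissue model.

The penalty mixing and strength are chosen once on the full dataset by
internal cross-validation over a small l1-ratio grid and then held fixed
across every bootstrap fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV

from tissueclock.containers import BetaMatrix, ages_for

#: |coefficient| above which a probe counts as present in a fit.
COEF_TOLERANCE = 1e-8
#: l1-ratio grid for the one-time internal CV.
L1_RATIO_GRID = (0.2, 0.5, 0.8)


class StabilityError(RuntimeError):
    pass


def choose_penalties(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratios=L1_RATIO_GRID,
    cv: int = 5,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Cross-validated (penalty_mix, penalty_strength) on the full data.

    Applies the one-standard-error rule: among (l1_ratio, alpha) pairs
    whose mean CV error is within one standard error of the overall
    minimum, the sparsest (largest alpha) is chosen. The plain CV
    minimum tends to under-penalize on noise-dominated data, which would
    let unstable probes ride through every bootstrap.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNetCV(
            l1_ratio=list(l1_ratios),
            alphas=30,
            cv=cv,
            random_state=seed,
            max_iter=5000,
        )
        model.fit(X, y)
    # mse_path_: (n_l1_ratios, n_alphas, n_folds); alphas_: (n_l1, n_alphas)
    mse = model.mse_path_
    mean = mse.mean(axis=2)
    se = mse.std(axis=2, ddof=1) / np.sqrt(mse.shape[2])
    i, j = np.unravel_index(np.argmin(mean), mean.shape)
    cutoff = mean[i, j] + se[i, j]
    alphas = np.atleast_2d(model.alphas_)
    if alphas.shape[0] == 1 and mean.shape[0] > 1:
        alphas = np.repeat(alphas, mean.shape[0], axis=0)
    ok = np.argwhere(mean <= cutoff)
    best = max(ok, key=lambda ij: alphas[ij[0], ij[1]])
    return float(list(l1_ratios)[best[0]]), float(alphas[best[0], best[1]])


def bootstrap_elastic_net(
    mat: BetaMatrix,
    samples: pd.DataFrame,
    n_boot: int = 500,
    freq_threshold: float = 0.95,
    penalty_mix: float | None = None,
    penalty_strength: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Selection frequencies of probes across bootstrap elastic-net fits.

    Parameters
    ----------
    mat
        Beta matrix restricted to the FDR-passing probes (no missing
        values).
    samples
        Sample table supplying chronological ages.
    n_boot
        Number of bootstrap resamples (reference protocol: 500).
    freq_threshold
        A probe is flagged selected iff its frequency is strictly greater
        than this.
    penalty_mix, penalty_strength
        Elastic-net l1 ratio and overall strength. When either is None
        both are chosen by :func:`choose_penalties` on the full data.
    seed
        Seeds resampling (and the internal CV when used).

    Returns
    -------
    DataFrame indexed by probe ID with columns ``selection_frequency``,
    ``mean_coefficient`` (mean over all fits, zeros included) and
    ``selected``, plus attrs recording the penalties and redraw count.
    """
    if mat.shape[0] < 1:
        raise StabilityError("no probes to select from")
    if n_boot < 1:
        raise StabilityError("n_boot must be >= 1")
    if not 0.0 <= freq_threshold <= 1.0:
        raise StabilityError("freq_threshold must lie in [0, 1]")
    ages = ages_for(mat, samples)
    X = mat.values.to_numpy().T  # samples x probes
    n, p = X.shape

    if penalty_mix is None or penalty_strength is None:
        penalty_mix, penalty_strength = choose_penalties(X, ages, seed=seed)

    rng = np.random.default_rng(seed)
    counts = np.zeros(p, dtype=int)
    coef_sum = np.zeros(p)
    redraws = 0
    max_redraws = max(1, int(0.1 * n_boot))
    est = ElasticNet(
        alpha=penalty_strength, l1_ratio=penalty_mix, max_iter=5000, warm_start=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_boot):
            while True:
                idx = rng.integers(0, n, size=n)
                if np.ptp(ages[idx]) > 0:
                    break
                redraws += 1
                if redraws > max_redraws:
                    raise StabilityError(
                        "more than 10% of bootstrap resamples had zero age "
                        "variance; the cohort is too small or too uniform"
                    )
            est.fit(X[idx], ages[idx])
            support = np.abs(est.coef_) > COEF_TOLERANCE
            counts += support
            coef_sum += est.coef_

    freq = counts / n_boot
    out = pd.DataFrame(
        {
            "selection_frequency": freq,
            "mean_coefficient": coef_sum / n_boot,
            "selected": freq > freq_threshold,
        },
        index=mat.probe_ids,
    )
    out.attrs.update(
        penalty_mix=penalty_mix,
        penalty_strength=penalty_strength,
        n_boot=n_boot,
        freq_threshold=freq_threshold,
        redraws=redraws,
    )
    return out


def select_markers(stability: pd.DataFrame) -> list[str]:
    """Probe IDs with frequency strictly above the threshold.

    Sorted by frequency descending, ties broken by probe ID. An empty
    result is valid (no stable markers).
    """
    if len(stability) == 0:
        return []
    sel = stability[stability["selected"]]
    sel = sel.sort_index(kind="mergesort").sort_values(
        "selection_frequency", ascending=False, kind="mergesort"
    )
    return sel.index.tolist()
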