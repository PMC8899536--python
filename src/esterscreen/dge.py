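"""Two-library digital-gene-expression testing on pooled read counts.

Implements the Audic–Claverie exact test for comparing a gene's read
counts between two sequencing libraries.  Each gene's count in one
library is modelled as Poisson with unknown rate lambda; conditioning on
the count ``x`` observed in library 1, the count ``y`` in library 2
follows the conditional distribution

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

where N1 and N2 are the total numbers of uniquely aligned reads in the
two libraries.  This is a negative-binomial law with ``x + 1`` successes
and success probability ``N1/(N1+N2)``, which is how the cumulative is
evaluated here.  A two-sided p-value doubles the lower cumulative tail,
or its complement when the cumulative exceeds one half.

Fold changes are ratios of library-size-normalised counts; genes are
called differentially transcribed when the normalised ratio is strictly
more than twofold in either direction and the (FDR-adjusted) p-value
clears the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestConfig",
    "AudicClaverieDE",
    "poisson_pmf",
    "ac_pmf",
    "ac_cumulative",
    "ac_two_sided_p",
    "fold_change",
    "benjamini_hochberg",
    "test_library",
]

RESULT_COLUMNS = [
    "gene_id",
    "x",
    "y",
    "fold_change",
    "p_two_sided",
    "fdr",
    "direction",
    "is_de",
]


@dataclass
class TestConfig:
    """Settings for the differential-transcription call.

    fold_threshold
        Normalised ratio that must be strictly exceeded (in either
        direction) for a gene to be called differentially transcribed.
    alpha
        Significance level applied to the FDR (or raw p when
        ``use_fdr`` is false).  Set ``use_fdr=False`` and ``alpha=1.0``
        for a fold-change-only call.
    pseudocount
        Added to both counts of a gene when either count is zero, so
        the ratio stays finite; never applied when both counts are
        positive.
    """

    fold_threshold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 0.5
    use_fdr: bool = True

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError(f"fold_threshold must be > 1, got {self.fold_threshold}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount}")


def _check_counts(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("read counts must be non-negative")
    return x, y


def _check_libsizes(n1: float, n2: float) -> None:
    if n1 < 1 or n2 < 1:
        raise ValueError(f"library sizes must be >= 1, got n1={n1}, n2={n2}")


def poisson_pmf(x, lam) -> np.ndarray | float:
    """Poisson probability of ``x`` events at rate ``lam``, via log-gamma."""
    x = np.asarray(x, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = -lam + x * np.log(lam) - gammaln(x + 1)
    # lam == 0: pmf is 1 at x == 0, else 0
    logp = np.where(lam == 0, np.where(x == 0, 0.0, -np.inf), logp)
    out = np.exp(logp)
    return out.item() if out.ndim == 0 else out


def ac_pmf(x, y, n1: float, n2: float) -> np.ndarray | float:
    """Conditional probability p(y|x) of the two-library count pair.

    Evaluated entirely in log space through log-gamma, so it stays
    finite for totals up to at least 1e7 reads per gene.
    """
    x, y = _check_counts(x, y)
    _check_libsizes(n1, n2)
    logr = np.log(n2) - np.log(n1)
    log1pr = np.log1p(n2 / n1)
    logp = (
        y * logr
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log1pr
    )
    out = np.exp(logp)
    return out.item() if out.ndim == 0 else out


def ac_cumulative(x, y, n1: float, n2: float) -> np.ndarray | float:
    """Lower cumulative sum_{i=0..y} p(i|x).

    Uses the negative-binomial identity: the conditional law of y given
    x is NB(x + 1, N1/(N1+N2)), so the cumulative is a regularised
    incomplete beta rather than an explicit term-by-term sum.  At the
    symmetric point x == y with equal library sizes the cumulative is
    exactly one half (in the first 2x+1 trials of the underlying
    Bernoulli scheme, heads-majority and tails-majority are equally
    likely); that value is returned exactly.
    """
    x, y = _check_counts(x, y)
    _check_libsizes(n1, n2)
    p_succ = n1 / (n1 + n2)
    s = nbinom.cdf(y, x + 1, p_succ)
    if n1 == n2:
        s = np.where(x == y, 0.5, s)
    return s.item() if np.ndim(s) == 0 else s


def ac_two_sided_p(x, y, n1: float, n2: float) -> np.ndarray | float:
    """Two-sided doubling p-value: 2*min(cumulative, 1 - cumulative).

    The upper branch is computed from the negative-binomial survival
    function directly rather than by subtraction, so neither tail loses
    precision.  The result is capped at 1 and is exactly 1 when x == y
    with equal library sizes.
    """
    x, y = _check_counts(x, y)
    _check_libsizes(n1, n2)
    p_succ = n1 / (n1 + n2)
    lower = nbinom.cdf(y, x + 1, p_succ)
    upper = nbinom.sf(y, x + 1, p_succ)  # P(Y > y) = 1 - lower
    p = 2.0 * np.minimum(lower, upper)
    if n1 == n2:
        p = np.where(x == y, 1.0, p)
    # extreme divergences underflow to 0; keep the result in (0, 1]
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p.item() if np.ndim(p) == 0 else p


def fold_change(x, y, n1: float, n2: float, pseudocount: float = 0.5):
    """Library-size-normalised ratio ((x/N1)) / ((y/N2)).

    The pseudocount is added to *both* counts of a gene, and only when
    either count is zero; genes with two positive counts are left
    untouched.  With a zero pseudocount, zero counts raise.
    """
    x, y = _check_counts(x, y)
    _check_libsizes(n1, n2)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    needs_pc = (x == 0) | (y == 0)
    if pseudocount == 0 and np.any(needs_pc):
        raise ZeroDivisionError(
            "zero count with zero pseudocount gives an undefined ratio"
        )
    pc = np.where(needs_pc, pseudocount, 0.0)
    out = ((x + pc) / n1) / ((y + pc) / n2)
    return out.item() if out.ndim == 0 else out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p-value list must be non-empty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class AudicClaverieDE(BaseEstimator):
    """Per-gene differential-transcription caller for two pooled libraries.

    scikit-learn-style estimator: construct with the calling policy,
    ``fit`` on a count table, read the per-gene table off ``results_``.

    Parameters
    ----------
    fold_threshold : float, default 2.0
        Strict threshold on the normalised fold change.
    alpha : float, default 0.05
        Significance level for the FDR (or raw p-value).
    pseudocount : float, default 0.5
        Added to both counts when either is zero.
    use_fdr : bool, default True
        Gate the call on the BH-adjusted p-value; if False, on the raw
        two-sided p-value.
    n1, n2 : int or None
        Library sizes (total uniquely aligned reads).  If None, each is
        taken as the column sum of the fitted count table.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per gene: gene_id, x, y, fold_change, p_two_sided,
        fdr, direction ('up'/'down'/'none'), is_de.
    n1_, n2_ : int
        Library sizes actually used.
    """

    def __init__(
        self,
        fold_threshold: float = 2.0,
        alpha: float = 0.05,
        pseudocount: float = 0.5,
        use_fdr: bool = True,
        n1: int | None = None,
        n2: int | None = None,
    ):
        self.fold_threshold = fold_threshold
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.use_fdr = use_fdr
        self.n1 = n1
        self.n2 = n2

    def fit(self, X: pd.DataFrame, y=None) -> "AudicClaverieDE":
        """Run the test on a count table.

        ``X`` must have columns gene_id, count_group1, count_group2.
        """
        config = TestConfig(
            fold_threshold=self.fold_threshold,
            alpha=self.alpha,
            pseudocount=self.pseudocount,
            use_fdr=self.use_fdr,
        )
        required = {"gene_id", "count_group1", "count_group2"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if X["gene_id"].duplicated().any():
            dupes = X.loc[X["gene_id"].duplicated(), "gene_id"].unique()
            raise ValueError(f"duplicate gene_id values: {list(dupes[:5])}")
        if len(X) == 0:
            raise ValueError("count table is empty")

        x = X["count_group1"].to_numpy()
        yv = X["count_group2"].to_numpy()
        n1 = int(self.n1) if self.n1 is not None else int(x.sum())
        n2 = int(self.n2) if self.n2 is not None else int(yv.sum())
        _check_libsizes(n1, n2)
        if np.any(x > n1) or np.any(yv > n2):
            raise ValueError("a gene's count exceeds its library size")

        fc = np.atleast_1d(fold_change(x, yv, n1, n2, config.pseudocount))
        p = np.atleast_1d(ac_two_sided_p(x, yv, n1, n2))
        fdr = benjamini_hochberg(p)

        norm1 = x / n1
        norm2 = yv / n2
        direction = np.where(norm1 > norm2, "up", np.where(norm1 < norm2, "down", "none"))
        fold_ok = (fc > config.fold_threshold) | (fc < 1.0 / config.fold_threshold)
        sig = fdr <= config.alpha if config.use_fdr else p <= config.alpha
        is_de = fold_ok & sig

        self.results_ = pd.DataFrame(
            {
                "gene_id": X["gene_id"].to_numpy(),
                "x": x,
                "y": yv,
                "fold_change": fc,
                "p_two_sided": p,
                "fdr": fdr,
                "direction": direction,
                "is_de": is_de,
            },
            columns=RESULT_COLUMNS,
        )
        self.n1_ = n1
        self.n2_ = n2
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).results_


def test_library(counts: pd.DataFrame, n1: int, n2: int, config: TestConfig | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`AudicClaverieDE`.

    ``counts`` has columns gene_id, count_group1, count_group2; returns
    the per-gene result table.
    """
    config = config or TestConfig()
    est = AudicClaverieDE(
        fold_threshold=config.fold_threshold,
        alpha=config.alpha,
        pseudocount=config.pseudocount,
        use_fdr=config.use_fdr,
        n1=n1,
        n2=n2,
    )
    return est.fit_transform(counts)
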