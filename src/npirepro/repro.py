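"""NPI-bootstrap reproducibility of a two-group test (NPI-B-RP).

The reproducibility probability of a test is the probability that an
identically repeated experiment — same sample sizes, same test, same level —
would reach the same reject / not-reject outcome. It is estimated here by
NPI bootstrap: the original test is performed once; then, in each of ``h``
runs, ``N`` pairs of NPI-B future samples (one per group, of the original
group sizes, each group using its own max-gap support bounds) are drawn and
tested, and the run's ``rp_k`` is the fraction of the ``N`` replicate tests
that match the original outcome. The mean of ``rp_1..rp_h`` is the reported
NPI-B-RP; min and max quantify the Monte-Carlo spread across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .npi import Bounds, Sample, _ensure_strict, compute_bounds, npi_b_sample_matrix
from .stats import TestResult, effect_stats, t_test_upper, t_test_upper_matrix, wmt_upper, wmt_upper_matrix

__all__ = ["RPConfig", "TestReproducibility", "TestReproducibilityResults"]

_TESTS = {
    "t": (t_test_upper, t_test_upper_matrix),
    "wmt": (wmt_upper, wmt_upper_matrix),
}


@dataclass(frozen=True)
class RPConfig:
    """Settings for the reproducibility bootstrap.

    N : bootstrap sample pairs per run (default 1000)
    h : number of runs (default 100)
    alpha : significance level (default 0.05)
    test : "t" (pooled upper-sided t-test) or "wmt"
    seed : master seed; run k uses the k-th spawned child stream, so any
        single run is reproducible in isolation
    """

    N: int = 1000
    h: int = 100
    alpha: float = 0.05
    test: str = "t"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1 or self.h < 1:
            raise ValueError("N and h must be >= 1")
        if self.test not in _TESTS:
            raise ValueError(f"unknown test {self.test!r}; expected 't' or 'wmt'")


class TestReproducibility:
    """Reproducibility model for one upper-sided two-group comparison.

    Parameters
    ----------
    x, y : Sample or array-like
        The two observed groups; x is the group hypothesised to have the
        larger mean (H1: mu_x > mu_y). Ties are broken automatically.
    test : {"t", "wmt"}
    alpha : float
        Significance level for every test, original and bootstrap.

    Examples
    --------
    >>> model = TestReproducibility([3.1, 2.9, 3.4], [1.0, 1.2, 0.8])
    >>> res = model.fit(N=200, h=20, seed=7)
    >>> 0 <= res.rp_mean <= 1
    True
    """

    __test__ = False  # not a pytest case, despite the Test* name

    def __init__(self, x, y, test: str = "t", alpha: float = 0.05):
        self.x = _ensure_strict(x if isinstance(x, Sample) else Sample("x", x))
        self.y = _ensure_strict(y if isinstance(y, Sample) else Sample("y", y))
        if test not in _TESTS:
            raise ValueError(f"unknown test {test!r}; expected 't' or 'wmt'")
        self.test = test
        self.alpha = float(alpha)
        self.bounds_x: Bounds = compute_bounds(self.x)
        self.bounds_y: Bounds = compute_bounds(self.y)

    def original_test(self) -> TestResult:
        return _TESTS[self.test][0](self.x, self.y, self.alpha)

    def fit(self, N: int = 1000, h: int = 100, seed: int | None = None) -> "TestReproducibilityResults":
        """Run the reproducibility bootstrap.

        Parameters
        ----------
        N : int
            Bootstrap pairs per run.
        h : int
            Number of runs; the reported NPI-B-RP is the mean over runs.
        seed : int, optional
            Master seed for the numpy bit generator.
        """
        config = RPConfig(N=N, h=h, alpha=self.alpha, test=self.test, seed=seed)
        original = self.original_test()
        matrix_test = _TESTS[self.test][1]
        nx, ny = self.x.n, self.y.n

        rp = np.empty(h)
        children = np.random.SeedSequence(seed).spawn(h)
        for k in range(h):
            rng = np.random.default_rng(children[k])
            X = npi_b_sample_matrix(self.x.values, self.bounds_x, nx, N, rng)
            Y = npi_b_sample_matrix(self.y.values, self.bounds_y, ny, N, rng)
            p = matrix_test(X, Y)
            rejected = p < self.alpha
            rp[k] = np.mean(rejected == original.reject)
        return TestReproducibilityResults(self, config, original, rp)


class TestReproducibilityResults:
    """Per-run reproducibility proportions and their summary.

    Attributes
    ----------
    rp_values : ndarray of shape (h,)
        The per-run proportions rp_1..rp_h.
    rp_mean : float
        THE reported NPI-B-RP value.
    rp_min, rp_max : float
        Spread of the per-run proportions.
    original : TestResult
        The test on the observed data, whose outcome the bootstrap matches.
    """

    def __init__(self, model: TestReproducibility, config: RPConfig, original: TestResult, rp_values: np.ndarray):
        self.model = model
        self.config = config
        self.original = original
        self.rp_values = np.asarray(rp_values, dtype=float)

    @property
    def rp_mean(self) -> float:
        return float(self.rp_values.mean())

    @property
    def rp_min(self) -> float:
        return float(self.rp_values.min())

    @property
    def rp_max(self) -> float:
        return float(self.rp_values.max())

    def to_dict(self) -> dict:
        """Report-ready summary (JSON-serialisable)."""
        eff = effect_stats(self.model.x, self.model.y)
        return {
            "pair": f"{self.model.x.label} vs {self.model.y.label}",
            "test": self.config.test,
            "alpha": self.config.alpha,
            "N": self.config.N,
            "h": self.config.h,
            "seed": self.config.seed,
            "original": {
                "statistic": self.original.statistic,
                "p_value": self.original.p_value,
                "reject": self.original.reject,
                "effect_size": eff.effect_size,
                "cohens_d": eff.cohens_d,
            },
            "rp_min": self.rp_min,
            "rp_mean": self.rp_mean,
            "rp_max": self.rp_max,
            "rp_values": self.rp_values.tolist(),
        }

    def summary(self) -> str:
        d = self.to_dict()
        o = d["original"]
        lines = [
            "NPI-B reproducibility of the "
            + ("t-test" if self.config.test == "t" else "Wilcoxon-Mann-Whitney test"),
            f"  pair: {d['pair']}   alpha = {self.config.alpha}   "
            f"N = {self.config.N}   h = {self.config.h}",
            f"  original: p = {o['p_value']:.4f}  "
            f"{'reject' if o['reject'] else 'not reject'}   "
            f"effect size = {o['effect_size']:.3f}   Cohen's d = {o['cohens_d']:.3f}",
            f"  NPI-B-RP: min = {self.rp_min:.3f}  mean = {self.rp_mean:.3f}  "
            f"max = {self.rp_max:.3f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TestReproducibilityResults rp_mean={self.rp_mean:.3f} "
            f"[{self.rp_min:.3f}, {self.rp_max:.3f}] test={self.config.test!r}>"
        )
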