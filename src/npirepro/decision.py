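"""Reproducibility of a final dose decision built from pairwise comparisons.

A dose-finding study compares g ordered groups (control first, increasing
concentration) through g-1 adjacent upper-sided t-tests, H1: the lower dose's
mean response exceeds the higher dose's (lower measurements = better drug
performance). The outcome is a Y/N string of length g-1 ('Y' = null
rejected). The decision rule selects the smallest dose whose comparison with
the next larger dose fails to reject — the first 'N' scanning from the
control end; an all-'Y' outcome selects the highest dose (no comparison
certifies a plateau; exposed as a convention).

The reproducibility of that decision (RPD) is estimated by NPI bootstrap:
N times, one future sample per group is drawn (own bounds, own size), the
g-1 tests are re-run with Benjamini-Hochberg adjustment across them, and the
resulting outcome vector is recorded. RPD is the fraction of runs whose
outcome vector maps to the same selected dose as the original analysis.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .npi import Sample, _ensure_strict, compute_bounds, npi_b_sample_matrix
from .stats import bh_adjust, bh_adjust_matrix, t_test_upper, t_test_upper_matrix

__all__ = [
    "pairwise_outcomes",
    "final_decision",
    "shift_on_raw_scale",
    "render_tree",
    "DecisionReproducibility",
    "DecisionReproducibilityResults",
]


def _as_samples(groups) -> list[Sample]:
    out = []
    for i, g in enumerate(groups):
        s = g if isinstance(g, Sample) else Sample(str(i), g)
        out.append(_ensure_strict(s))
    if len(out) < 2:
        raise ValueError("need at least two groups for pairwise comparisons")
    return out


def pairwise_outcomes(groups, alpha: float = 0.05, adjust: bool = True):
    """Adjacent upper-sided t-tests over ordered dose groups.

    Comparison i tests lower-dose group i against higher-dose group i+1
    (H1: mu_lower > mu_higher). With ``adjust``, decisions use BH-adjusted
    p-values across the g-1 simultaneous tests.

    Returns
    -------
    outcome : str
        Y/N string of length g-1.
    raw_p, adj_p : ndarray
        Raw and BH-adjusted p-values (``adj_p is raw_p`` when not adjusting).
    """
    samples = _as_samples(groups)
    raw_p = np.array(
        [t_test_upper(a, b, alpha).p_value for a, b in zip(samples[:-1], samples[1:])]
    )
    adj_p = bh_adjust(raw_p) if adjust else raw_p
    outcome = "".join("Y" if p < alpha else "N" for p in adj_p)
    return outcome, raw_p, adj_p


def final_decision(outcome: str, labels) -> str:
    """Smallest dose whose comparison with the next dose does not reject.

    ``labels`` are the g group labels in dose order; ``outcome`` has length
    g-1. Returns the lower-dose label of the first 'N'; the highest-dose
    label if every comparison rejected.
    """
    labels = list(labels)
    if len(outcome) != len(labels) - 1:
        raise ValueError("outcome length must be number of groups minus one")
    if set(outcome) - {"Y", "N"}:
        raise ValueError("outcome may contain only 'Y' and 'N'")
    i = outcome.find("N")
    return labels[i] if i >= 0 else labels[-1]


def shift_on_raw_scale(values, delta: float) -> np.ndarray:
    """Shift log10-scale measurements by ``delta`` on the raw scale.

    Returns ``log10(10**v + delta)`` elementwise; the raw shifted values
    must stay positive.
    """
    v = np.asarray(values, dtype=float)
    raw = 10.0 ** v + delta
    if np.any(raw <= 0):
        raise ValueError("shift makes some raw values non-positive")
    return np.log10(raw)


def render_tree(table: dict | Counter, highlight: str | None = None) -> str:
    """Text reproducibility tree from an outcome-vector frequency table.

    Each depth splits on the next comparison's Y/N; a node's weight is the
    summed count of all vectors sharing its prefix, so children's weights sum
    exactly to their parent's. Prefixes on the path to ``highlight`` are
    marked with '*'.
    """
    if not table:
        raise ValueError("empty frequency table")
    depth = len(next(iter(table)))
    total = sum(table.values())
    lines = [f"runs: {total}"]

    def walk(prefix: str) -> None:
        for sym in ("Y", "N"):
            p = prefix + sym
            w = sum(c for v, c in table.items() if v.startswith(p))
            if w == 0:
                continue
            mark = " *" if highlight is not None and highlight.startswith(p) else ""
            pad = p + "." * (depth - len(p))
            lines.append("  " * len(p) + f"{pad}  {w}{mark}")
            if len(p) < depth:
                walk(p)

    walk("")
    return "\n".join(lines)


class DecisionReproducibility:
    """Reproducibility model for the final decision of a dose-finding study.

    Parameters
    ----------
    groups : sequence of Sample (or arrays), or a Dataset
        Ordered dose groups, control first.
    alpha : float
        Level for every pairwise test.
    adjust : bool
        Apply BH adjustment across the g-1 tests — in the original analysis
        and inside every bootstrap run (mirroring the original analysis).
    all_reject_label : str, optional
        Decision for an all-'Y' outcome; defaults to the highest dose.
    """

    def __init__(self, groups, alpha: float = 0.05, adjust: bool = True,
                 all_reject_label: str | None = None):
        if hasattr(groups, "groups"):  # io.Dataset
            groups = groups.groups
        self.samples = _as_samples(groups)
        self.labels = [s.label for s in self.samples]
        self.g = len(self.samples)
        self.alpha = float(alpha)
        self.adjust = bool(adjust)
        self.bounds = [compute_bounds(s) for s in self.samples]
        self._labels_for_decision = list(self.labels)
        if all_reject_label is not None:
            self._labels_for_decision[-1] = all_reject_label

    def decide(self, outcome: str) -> str:
        return final_decision(outcome, self._labels_for_decision)

    def original(self):
        """Outcome, decision and p-values of the observed data."""
        outcome, raw_p, adj_p = pairwise_outcomes(self.samples, self.alpha, self.adjust)
        return outcome, self.decide(outcome), raw_p, adj_p

    def fit(self, N: int = 1000, seed: int | None = None) -> "DecisionReproducibilityResults":
        """Run the decision-reproducibility bootstrap with N runs."""
        if N < 1:
            raise ValueError("N must be >= 1")
        outcome, decision, raw_p, adj_p = self.original()
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        boots = [
            npi_b_sample_matrix(s.values, b, s.n, N, rng)
            for s, b in zip(self.samples, self.bounds)
        ]
        P = np.column_stack(
            [t_test_upper_matrix(boots[i], boots[i + 1]) for i in range(self.g - 1)]
        )
        if self.adjust:
            P = bh_adjust_matrix(P)
        reject = P < self.alpha
        vectors = ["".join("Y" if r else "N" for r in row) for row in reject]
        table = Counter(vectors)
        decisions = {v: self.decide(v) for v in table}
        rpd = sum(c for v, c in table.items() if decisions[v] == decision) / N
        return DecisionReproducibilityResults(
            model=self,
            N=N,
            seed=seed,
            rpd=rpd,
            table=table,
            original_outcome=outcome,
            original_decision=decision,
            decision_map=decisions,
            raw_p=raw_p,
            adj_p=adj_p,
        )


class DecisionReproducibilityResults:
    """Frequency table of bootstrap outcome vectors and the RPD estimate."""

    def __init__(self, model, N, seed, rpd, table, original_outcome,
                 original_decision, decision_map, raw_p, adj_p):
        self.model = model
        self.N = N
        self.seed = seed
        self.rpd = rpd
        self.table = table
        self.original_outcome = original_outcome
        self.original_decision = original_decision
        self.decision_map = decision_map
        self.raw_p = raw_p
        self.adj_p = adj_p

    def frequency_frame(self) -> pd.DataFrame:
        """Two-column outcome/count table, descending count, ties lexicographic."""
        rows = sorted(self.table.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["outcome", "count"])

    def render_tree(self) -> str:
        return render_tree(self.table, highlight=self.original_outcome)

    def to_dict(self) -> dict:
        return {
            "labels": self.model.labels,
            "alpha": self.model.alpha,
            "adjust": self.model.adjust,
            "N": self.N,
            "seed": self.seed,
            "raw_p": list(map(float, self.raw_p)),
            "adjusted_p": list(map(float, self.adj_p)),
            "original_outcome": self.original_outcome,
            "original_decision": self.original_decision,
            "rpd": self.rpd,
            "frequency_table": dict(sorted(self.table.items(), key=lambda kv: (-kv[1], kv[0]))),
            "decision_map": self.decision_map,
        }

    def summary(self) -> str:
        pairs = [f"{a} vs {b}" for a, b in zip(self.model.labels[:-1], self.model.labels[1:])]
        lines = [
            "NPI-B reproducibility of the final dose decision",
            f"  groups: {', '.join(self.model.labels)}   alpha = {self.model.alpha}"
            f"   BH adjust = {self.model.adjust}   N = {self.N}",
            "  pairwise p-values (raw / adjusted):",
        ]
        for name, rp, ap in zip(pairs, self.raw_p, self.adj_p):
            lines.append(f"    {name:10s} {rp:.4f} / {ap:.4f}")
        lines += [
            f"  original outcome: {self.original_outcome}"
            f"   decision: dose {self.original_decision}",
            f"  RPD = {self.rpd:.3f}",
            "  most frequent outcome vectors:",
        ]
        for v, c in self.frequency_frame().head(5).itertuples(index=False):
            lines.append(f"    {v}  {c:5d}  -> dose {self.decision_map[v]}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DecisionReproducibilityResults rpd={self.rpd:.3f} "
            f"decision={self.original_decision!r} N={self.N}>"
        )
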