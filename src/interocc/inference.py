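"""Posterior summarization: inclusion probabilities, conditional effects, R-hat.

Variable selection yields two complementary statistics per candidate term: the
posterior inclusion probability (mean of the indicator w_k, the probability
that the best model contains the term) and the conditional effect summary
(posterior of beta_k restricted to draws with w_k = 1, reported with 85% and
95% equal-tailed credible intervals).  Directional confidence follows the
shrinkage-aware rule: flag a term when its 85% CRI excludes zero; the 95%
interval is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PosteriorDraws:
    """MCMC output: named parameter draws of shape (chains, iterations).

    ``coefficients`` lists the selectable coefficient ids; a coefficient
    ``c`` has beta draws under ``c`` and indicator draws under ``w:c``.
    Derived array indices are stored like any other parameter (names
    ``Nbar:<species>[<array>]`` / ``zbar:...``).
    """

    draws: dict
    coefficients: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {np.asarray(v).shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"parameter draws of unequal shape: {shapes}")
        self.draws = {k: np.asarray(v, dtype=float) for k, v in self.draws.items()}

    @property
    def names(self) -> list:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(f"unknown parameter {name!r}")
        return self.draws[name]

    def pooled(self, name: str) -> np.ndarray:
        """Draws concatenated across chains (chain 1 first)."""
        return self.get(name).reshape(-1)

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        """Write draws as a long CSV plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = []
        for name, arr in self.draws.items():
            c, t = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                               indexing="ij")
            frames.append(pd.DataFrame({"parameter": name, "chain": c.ravel(),
                                        "iteration": t.ravel(), "value": arr.ravel()}))
        pd.concat(frames, ignore_index=True).to_csv(directory / "draws.csv", index=False)
        meta = {"coefficients": self.coefficients, "manifest": self.manifest}
        (directory / "manifest.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        directory = Path(directory)
        df = pd.read_csv(directory / "draws.csv")
        draws = {}
        for name, block in df.groupby("parameter", sort=False):
            piv = block.pivot(index="chain", columns="iteration", values="value")
            draws[name] = piv.to_numpy()
        meta = json.loads((directory / "manifest.json").read_text())
        return cls(draws=draws, coefficients=meta["coefficients"],
                   manifest=meta["manifest"])


@dataclass
class EffectSummary:
    """Inclusion probability plus conditional-on-inclusion effect summary."""

    coefficient: str
    inclusion_prob: float
    n_conditional_draws: int
    cond_mean: float | None = None
    cond_sd: float | None = None
    cri85: tuple | None = None
    cri95: tuple | None = None
    directional_85: bool = False
    directional_95: bool = False
    low_conditional_draws: bool = False

    @property
    def empty(self) -> bool:
        return self.n_conditional_draws == 0


def inclusion_probability(draws: PosteriorDraws, coefficient: str) -> float:
    """Posterior probability that the model includes ``coefficient``."""
    w = draws.get(f"w:{coefficient}")
    return float(w.mean())


def _interval(x: np.ndarray, level: float, kind: str = "eti") -> tuple:
    if kind == "eti":
        lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)
    if kind == "hpd":  # shortest interval containing `level` mass
        xs = np.sort(x)
        m = max(1, int(np.ceil(level * xs.size)))
        if m >= xs.size:
            return float(xs[0]), float(xs[-1])
        widths = xs[m:] - xs[:-m]
        i = int(np.argmin(widths))
        return float(xs[i]), float(xs[i + m])
    raise ValueError(f"unknown interval kind {kind!r}")


def conditional_effect(draws: PosteriorDraws, coefficient: str,
                       min_draws: int = 100, interval: str = "eti") -> EffectSummary:
    """Summarize a coefficient's posterior conditional on its inclusion.

    Chains are pooled by concatenation before conditioning.  If the
    coefficient has no selection indicator (selection disabled), every draw
    counts as included.  With zero conditional draws an explicit empty
    summary is returned rather than NaNs.
    """
    beta = draws.pooled(coefficient)
    wname = f"w:{coefficient}"
    if wname in draws.draws:
        w = draws.pooled(wname)
        incl = float(w.mean())
        beta = beta[w == 1]
    else:
        incl = 1.0
    n = beta.size
    if n == 0:
        return EffectSummary(coefficient=coefficient, inclusion_prob=incl,
                             n_conditional_draws=0)
    cri85 = _interval(beta, 0.85, interval)
    cri95 = _interval(beta, 0.95, interval)
    return EffectSummary(
        coefficient=coefficient,
        inclusion_prob=incl,
        n_conditional_draws=n,
        cond_mean=float(beta.mean()),
        cond_sd=float(beta.std(ddof=1)) if n > 1 else 0.0,
        cri85=cri85,
        cri95=cri95,
        directional_85=(cri85[0] > 0) or (cri85[1] < 0),
        directional_95=(cri95[0] > 0) or (cri95[1] < 0),
        low_conditional_draws=n < min_draws,
    )


def gelman_rubin(draws, parameter: str | None = None) -> float:
    """Potential scale reduction factor (R-hat) from >= 2 chains.

    Classic between/within-chain variance ratio:
    R = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance
    and B/n the variance of chain means.  Chains with zero variance
    everywhere return 1.0 by convention (a constant is converged).
    """
    x = draws.get(parameter) if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, iterations) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 2:
        raise ValueError("R-hat requires at least 2 iterations per chain")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def rhat_report(draws: PosteriorDraws, threshold: float = 1.1) -> pd.DataFrame:
    """R-hat per recorded parameter with a convergence flag column."""
    rows = []
    for name in draws.names:
        x = draws.get(name)
        if x.shape[0] < 2:
            continue
        r = gelman_rubin(x)
        rows.append((name, r, r < threshold))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "converged"])


def summary_table(draws: PosteriorDraws, spec=None, interval: str = "eti") -> pd.DataFrame:
    """One row per selectable coefficient: w, conditional mean (sd), CRIs.

    Mirrors the reporting shape of covariate-selection tables: inclusion
    probability, conditional-on-inclusion mean and sd, 85% and 95% credible
    intervals, and directional-confidence flags at both levels.
    """
    rows = []
    for coef in draws.coefficients:
        s = conditional_effect(draws, coef, interval=interval)
        species, param, term = coef.split(".", 2)
        rows.append({
            "species": species, "parameter": param, "term": term,
            "inclusion_prob": s.inclusion_prob,
            "n_conditional": s.n_conditional_draws,
            "cond_mean": s.cond_mean, "cond_sd": s.cond_sd,
            "cri85_lo": None if s.empty else s.cri85[0],
            "cri85_hi": None if s.empty else s.cri85[1],
            "cri95_lo": None if s.empty else s.cri95[0],
            "cri95_hi": None if s.empty else s.cri95[1],
            "directional_85": s.directional_85,
            "directional_95": s.directional_95,
        })
    return pd.DataFrame(rows)


def write_summary_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
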