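"""Posterior and data summaries.

Marginal posterior model probabilities (partition visit frequencies),
interaction-inclusion probabilities, per-parameter posterior means with 95%
symmetric credible intervals, per-draw intraclass correlations, a
credible-interval overlap diagnostic, and the marginal Pearson correlations
between species used for exploratory data description.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .model import PanelData, intraclass_correlation
from .rjmcmc import ChainOutput

__all__ = [
    "model_probabilities",
    "nu_inclusion_probabilities",
    "parameter_summary",
    "icc_summary",
    "ci_overlap",
    "marginal_correlations",
]


def _check_chain(chain: ChainOutput) -> None:
    if chain.n_draws < 1:
        raise ValueError("chain is empty")


def model_probabilities(chain: ChainOutput, family: str) -> pd.DataFrame:
    """Empirical posterior probability of each visited partition for one
    shareable family, sorted descending; labels use the brace style
    "{bt, gt}, {ct}"."""
    _check_chain(chain)
    if family not in chain.partitions:
        raise KeyError(f"unknown family {family!r}; have {chain.families}")
    parts = chain.partitions[family]
    counts: dict = {}
    for p in parts:
        counts[p] = counts.get(p, 0) + 1
    rows = [
        {
            "model": p.label(chain.species),
            "probability": c / len(parts),
        }
        for p, c in counts.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        "probability", ascending=False, kind="stable"
    )
    return out.reset_index(drop=True)


def nu_inclusion_probabilities(chain: ChainOutput) -> pd.DataFrame:
    """Per ordered species pair: posterior inclusion probability of
    nu[l, s], plus the conditional (on inclusion) posterior mean and 95%
    CI.  Never-included pairs report NaN summaries (printed as NA)."""
    _check_chain(chain)
    inc = chain.draws["nu_included"]
    vals = chain.draws["nu"]
    n_s = len(chain.species)
    rows = []
    for l in range(n_s):
        for s in range(n_s):
            m = inc[:, l, s]
            p = float(m.mean())
            if m.any():
                v = vals[m, l, s]
                mean, lo, hi = (
                    float(v.mean()),
                    float(np.quantile(v, 0.025)),
                    float(np.quantile(v, 0.975)),
                )
            else:
                mean = lo = hi = math.nan
            rows.append(
                {
                    "effect_of": chain.species[l],
                    "on": chain.species[s],
                    "kind": "density_dependence" if l == s else "interaction",
                    "inclusion_probability": p,
                    "mean_given_included": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def parameter_summary(chain: ChainOutput) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% CI per scalar parameter.

    Shared families are summarized per (family, species) by reading the
    species' block value in every draw, so species sharing a block in all
    draws report identical rows.
    """
    _check_chain(chain)
    rows = []

    def add(name, draws_1d):
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(draws_1d)),
                "ci_low": float(np.quantile(draws_1d, 0.025)),
                "ci_high": float(np.quantile(draws_1d, 0.975)),
            }
        )

    sp = chain.species
    for s, name in enumerate(sp):
        add(f"alpha[{name}]", chain.draws["alpha"][:, s])
    for fam in chain.families:
        for s, name in enumerate(sp):
            add(f"{fam}[{name}]", chain.draws[fam][:, s])
    add("sigma2_eps", chain.draws["sigma2_eps"])
    for s, name in enumerate(sp):
        add(f"sigma2[{name}]", chain.draws["sigma2_s"][:, s])
    return pd.DataFrame(rows)


def icc_summary(chain: ChainOutput) -> pd.DataFrame:
    """Per-species intraclass correlation: the ICC is computed draw by draw
    from that draw's variance components and then averaged (mean of ratios,
    not ratio of posterior means), with an equal-tailed 95% CI."""
    _check_chain(chain)
    s2e = chain.draws["sigma2_eps"]
    rows = []
    for s, name in enumerate(chain.species):
        icc = intraclass_correlation(s2e, chain.draws["sigma2_s"][:, s])
        icc = np.atleast_1d(icc)
        rows.append(
            {
                "species": name,
                "mean": float(icc.mean()),
                "ci_low": float(np.quantile(icc, 0.025)),
                "ci_high": float(np.quantile(icc, 0.975)),
            }
        )
    return pd.DataFrame(rows)


def ci_overlap(interval_a: tuple[float, float], interval_b: tuple[float, float]) -> float:
    """Proportion of overlap of two credible intervals.

    (min(high) - max(low)) divided by the narrower interval's width;
    negative values indicate disjoint intervals, 1 means the narrower
    interval is contained (identical intervals give exactly 1).
    """
    (lo_a, hi_a), (lo_b, hi_b) = interval_a, interval_b
    if not (lo_a < hi_a and lo_b < hi_b):
        raise ValueError("intervals must have positive width")
    overlap = min(hi_a, hi_b) - max(lo_a, lo_b)
    return overlap / min(hi_a - lo_a, hi_b - lo_b)


def marginal_correlations(data: PanelData) -> pd.DataFrame:
    """Pairwise Pearson correlations between species, marginal over sites
    and over years.

    "site" rows correlate per-site means taken across years; "year" rows
    correlate per-year means taken across sites (using, per year, the sites
    observing that year).  Two-sided p-values from the t transform.
    """
    if data.n_sites < 3:
        raise ValueError("need at least 3 sites")
    off = data.offsets
    n_s = data.n_species
    site_means = np.empty((n_s, data.n_sites))
    for i in range(data.n_sites):
        site_means[:, i] = data.y[:, off[i] : off[i + 1]].mean(axis=1)
    years = sorted(
        {int(t) for i in range(data.n_sites) for t in data.site_years(i)}
    )
    if len(years) < 3:
        raise ValueError("need at least 3 years")
    year_means = np.empty((n_s, len(years)))
    for k, t in enumerate(years):
        cols = []
        for i in range(data.n_sites):
            if data.window_start[i] <= t < data.window_start[i] + data.window_len[i]:
                cols.append(off[i] + t - data.window_start[i])
        year_means[:, k] = data.y[:, cols].mean(axis=1)
    rows = []
    for a in range(n_s):
        for b in range(a + 1, n_s):
            for scope, m in (("site", site_means), ("year", year_means)):
                r, p = stats.pearsonr(m[a], m[b])
                rows.append(
                    {
                        "species_a": data.species[a],
                        "species_b": data.species[b],
                        "across": scope,
                        "correlation": float(r),
                        "p_value": float(p),
                    }
                )
    return pd.DataFrame(rows)
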