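"""Synthetic clinical cohorts matched to published group statistics.

The study reports only group-level summaries (median and interquartile
range per parameter per diagnosis group), so cohorts are emulated by
fitting simple two-parameter distributions to those quartiles: log-normal
for the strictly positive, right-skewed parameters (AC, ESD, ESC) and
normal for SoS (narrow relative spread).  For a log-normal,
``mu = ln(median)`` and ``sigma = ln(q3/q1) / (2 * 0.67449)``; for a
normal, ``mean = median`` and ``sd = (q3 - q1) / (2 * 0.67449)`` (0.67449
being the standard normal upper quartile).

Within a group the four parameters are drawn independently by default —
the true correlations are not published — with an optional Gaussian-copula
correlation hook.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "table4_summaries",
    "fit_distribution_from_quartiles",
    "sample_cohort",
]

#: upper-quartile z of the standard normal
_Z75 = 0.6744897501960817

PARAM_FAMILIES = {
    "ac": "log-normal",
    "sos": "normal",
    "esd": "log-normal",
    "esc": "log-normal",
}


@dataclass
class GroupSummary:
    """Median and quartiles for each parameter in each diagnosis group."""

    table: pd.DataFrame  # columns: parameter, group, median, q1, q3

    def __post_init__(self) -> None:
        need = {"parameter", "group", "median", "q1", "q3"}
        if not need <= set(self.table.columns):
            raise ValueError(f"summary table must have columns {sorted(need)}")
        bad = self.table[
            (self.table["q1"] > self.table["median"])
            | (self.table["median"] > self.table["q3"])
            | (self.table[["median", "q1", "q3"]] <= 0).any(axis=1)
        ]
        if len(bad):
            raise ValueError("quartiles must satisfy 0 < q1 <= median <= q3")

    def row(self, parameter: str, group: str) -> tuple[float, float, float]:
        sel = self.table[
            (self.table["parameter"] == parameter) & (self.table["group"] == group)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique summary for {parameter}/{group}")
        r = sel.iloc[0]
        return float(r["median"]), float(r["q1"]), float(r["q3"])


def table4_summaries() -> GroupSummary:
    """The packaged benign/malignant (and IDC/DCIS) group summaries."""
    with resources.files("pwqus.data").joinpath("table4_summaries.csv").open() as fh:
        return GroupSummary(pd.read_csv(fh))


def fit_distribution_from_quartiles(
    median: float, q1: float, q3: float, family: str = "log-normal"
) -> dict[str, float]:
    """Distribution parameters reproducing the given quartiles.

    Degenerate quartiles (q1 == q3) give a point mass (sigma/sd = 0).
    """
    if q1 > median or median > q3:
        raise ValueError("need q1 <= median <= q3")
    if family == "log-normal":
        if min(median, q1, q3) <= 0:
            raise ValueError("log-normal requires positive quartiles")
        return {"mu": float(np.log(median)), "sigma": float(np.log(q3 / q1) / (2 * _Z75))}
    if family == "normal":
        return {"mean": float(median), "sd": float((q3 - q1) / (2 * _Z75))}
    raise ValueError(f"unknown family {family!r}")


def _draw(rng, params, family, n):
    if family == "log-normal":
        return rng.lognormal(params["mu"], params["sigma"], n)
    return rng.normal(params["mean"], params["sd"], n)


def sample_cohort(
    n_benign: int = 32,
    n_malignant: int = 23,
    summaries: GroupSummary | None = None,
    seed: int = 0,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Labeled synthetic lesion table matched to the group summaries.

    Defaults mirror the clinical cohort composition (32 benign /
    23 malignant).  ``correlation``, if given, is a 4 x 4 matrix applied
    through a Gaussian copula in parameter order (ac, sos, esd, esc);
    the default is independence.
    """
    summaries = summaries or table4_summaries()
    rng = np.random.default_rng(seed)
    frames = []
    for group, n in (("benign", n_benign), ("malignant", n_malignant)):
        if n == 0:
            continue
        if correlation is None:
            z = rng.standard_normal((n, 4))
        else:
            corr = np.asarray(correlation, dtype=float)
            if corr.shape != (4, 4):
                raise ValueError("correlation must be 4 x 4")
            z = rng.multivariate_normal(np.zeros(4), corr, size=n)
        u = stats.norm.cdf(z)
        cols = {}
        for j, param in enumerate(("ac", "sos", "esd", "esc")):
            family = PARAM_FAMILIES[param]
            p = fit_distribution_from_quartiles(*summaries.row(param, group), family)
            if family == "log-normal":
                cols[param] = np.exp(p["mu"] + p["sigma"] * stats.norm.ppf(u[:, j]))
            else:
                cols[param] = p["mean"] + p["sd"] * stats.norm.ppf(u[:, j])
        df = pd.DataFrame(cols)
        df["label"] = group
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["id", "ac", "sos", "esd", "esc", "label"])
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", np.arange(1, len(out) + 1))
    return out
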