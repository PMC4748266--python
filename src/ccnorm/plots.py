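"""Optional matplotlib views of sweep and population results.

Numeric CSV/JSON outputs are the primary artifacts; these plots are
conveniences for eyeballing the SPE-vs-CC_norm² divergence.
"""

from __future__ import annotations

from typing import Iterable

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .experiments import MetricReport, NoiseSweepResult


def plot_noise_sweep(result: NoiseSweepResult, ax=None):
    """SPE and CC_norm² against the noise level α, on one axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.alphas, result.spe_values, "o-", label="SPE")
    ax.plot(result.alphas, result.cc_norm_sq_values, "s-", label=r"$CC_{norm}^2$")
    ax.plot(result.alphas, result.cc_norm_values, "^--", label=r"$CC_{norm}$")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(r"noise level $\alpha$")
    ax.set_ylabel("score")
    ax.legend()
    return ax


def plot_spe_vs_ccnorm_sq(reports: Iterable[MetricReport], ax=None):
    """Scatter of SPE against signed CC_norm² with the y = x diagonal.

    The signed square (|CC_norm|·CC_norm) keeps anticorrelated units
    visible below zero; on real-style data the x-range stays positive
    while SPE extends unboundedly below.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xs, ys = [], []
    for r in reports:
        if r.cc_norm.is_defined and r.spe.is_defined:
            xs.append(abs(r.cc_norm.value) * r.cc_norm.value)
            ys.append(r.spe.value)
    ax.scatter(xs, ys, s=12, alpha=0.7)
    lim = [-1.0, 1.1]
    ax.plot(lim, lim, "k--", lw=0.8, label="SPE = $CC_{norm}^2$")
    ax.set_xlabel(r"$|CC_{norm}| \times CC_{norm}$")
    ax.set_ylabel("SPE")
    ax.legend()
    return ax
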