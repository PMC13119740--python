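"""Monte-Carlo robustness of a marker panel under assay failure.

KASP assays fail marker-wise (a bad primer loses the whole column), so the
simulation removes random marker subsets of size k from the panel and
recomputes the discrimination rate on what remains.  For each k a fixed
number of independent replicates is drawn; means and sample standard
deviations (n−1 denominator) summarise the decline.  A single root seed keys
an independent substream per (k, replicate), so results do not depend on
iteration order and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotype import GenotypeMatrix
from .panel import MarkerPanel
from .selection import DiscriminationPolicy, resolved_matrix

__all__ = ["RobustnessResult", "marker_failure_simulation", "robustness_plot_table"]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RobustnessResult:
    """Discrimination rate per number of removed markers.

    ``rates`` (when present) holds every replicate's rate, shape
    ``(len(k_values), reps)``; the k = 0 row is the exact full-panel rate.
    """

    k_values: list[int]
    mean: np.ndarray
    sd: np.ndarray
    reps: int
    seed: int
    panel_id: str | None = None
    rates: np.ndarray | None = None

    def to_table(self) -> pd.DataFrame:
        return robustness_plot_table(self)

    @classmethod
    def from_table(cls, table: pd.DataFrame, seed: int = 0, panel_id: str | None = None):
        """Rebuild the summary-level result from its long-format table."""
        t = table.sort_values("k")
        reps = int(t["reps"].iloc[0]) if "reps" in t else 0
        return cls(
            k_values=[int(k) for k in t["k"]],
            mean=t["mean_discrimination"].to_numpy(float),
            sd=t["sd"].to_numpy(float),
            reps=reps,
            seed=seed,
            panel_id=panel_id,
        )


class _PackedPanel:
    """Per-marker resolved-pair matrices packed to uint64 words for fast OR-reduce."""

    def __init__(self, gm: GenotypeMatrix, markers: list[str], policy: DiscriminationPolicy):
        n = gm.n_accessions
        self.n = n
        nbytes = -(-n // 8)
        pad = (-nbytes) % 8
        words = (nbytes + pad) // 8
        self.packed = np.zeros((len(markers), n * words), dtype=np.uint64)
        for jj, m in enumerate(markers):
            M = resolved_matrix(gm.marker_calls(m), policy)
            b = np.packbits(M, axis=1)
            if pad:
                b = np.pad(b, ((0, 0), (0, pad)))
            self.packed[jj] = b.reshape(-1).view(np.uint64)
        full = ~np.eye(n, dtype=bool)  # a unique accession is resolved from all others
        fb = np.packbits(full, axis=1)
        if pad:
            fb = np.pad(fb, ((0, 0), (0, pad)))
        self.target = fb.reshape(-1).view(np.uint64)
        self.words = words

    def rate(self, kept: np.ndarray) -> float:
        """Discrimination rate (2 d.p.) of the sub-panel indexed by ``kept``."""
        if len(kept):
            ored = np.bitwise_or.reduce(self.packed[kept], axis=0)
        else:
            ored = np.zeros_like(self.target)
        covered = (ored & self.target) == self.target
        unique = covered.reshape(self.n, self.words).all(axis=1)
        if self.n == 1:
            return 100.0  # single accession is trivially unique
        return _round2(100.0 * int(unique.sum()) / self.n)


def marker_failure_simulation(
    gm: GenotypeMatrix,
    panel: MarkerPanel | list[str],
    reps: int = 200,
    seed: int = 0,
    k_values: list[int] | None = None,
    policy: DiscriminationPolicy = DiscriminationPolicy.STRICT,
) -> RobustnessResult:
    """Simulate random failure of k panel markers for each k.

    ``k_values`` defaults to 1..len(panel)−1; k = 0 (the exact full-panel
    rate, sd 0) is always included as the baseline row.  Each replicate draws
    k markers to delete uniformly without replacement.
    """
    markers = list(panel.markers if isinstance(panel, MarkerPanel) else panel)
    if not markers:
        raise ConfigurationError("robustness simulation requires a non-empty panel")
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    p = len(markers)
    if k_values is None:
        k_values = list(range(1, p))
    for k in k_values:
        if k < 0 or k >= p:
            raise ConfigurationError(f"removal count k={k} must satisfy 0 <= k < panel size {p}")
    ks = [0] + [k for k in k_values if k != 0]

    packed = _PackedPanel(gm, markers, DiscriminationPolicy(policy))
    full_rate = packed.rate(np.arange(p))

    rates = np.empty((len(ks), reps), dtype=float)
    for ki, k in enumerate(ks):
        if k == 0:
            rates[ki, :] = full_rate
            continue
        for r in range(reps):
            rng = np.random.default_rng([seed, k, r])  # order-independent substream
            removed = rng.choice(p, size=k, replace=False)
            kept = np.setdiff1d(np.arange(p), removed)
            rates[ki, r] = packed.rate(kept)

    mean = rates.mean(axis=1)
    sd = rates.std(axis=1, ddof=1) if reps > 1 else np.zeros(len(ks))
    return RobustnessResult(
        k_values=ks, mean=mean, sd=sd, reps=reps, seed=seed, rates=rates
    )


def robustness_plot_table(result: RobustnessResult) -> pd.DataFrame:
    """Long-format (k, mean, sd, reps) table for plotting or export."""
    return pd.DataFrame(
        {
            "k": result.k_values,
            "mean_discrimination": result.mean,
            "sd": result.sd,
            "reps": result.reps,
        }
    )


def robustness_plot(result: RobustnessResult, path) -> None:
    """Mean discrimination vs markers removed, with sd error bars (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(result.k_values, result.mean, yerr=result.sd, fmt="ko", capsize=3, lw=1)
    ax.set_xlabel("markers removed")
    ax.set_ylabel("discrimination rate (%)")
    ax.set_title("Panel robustness under simulated marker failure")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
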