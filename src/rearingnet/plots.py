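"""Basic diagnostic plots (PNG) for the three standard figures.

These are working graphics, not publication artwork: a rarefaction
curve, a Whittaker rank-abundance plot (log abundance vs. rank), and a
two-column bipartite web with hosts on the left, flies on the right and
line widths scaled by interaction counts.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .community import RankAbundance, RarefactionCurve  # noqa: E402
from .network import InteractionMatrix  # noqa: E402
from .records import FlySpecies, PlantTaxon  # noqa: E402


def rarefaction_plot(curves: dict[str, RarefactionCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, c in curves.items():
        ax.plot(c.points["t"], c.points["expected_richness"], marker=".", label=label)
        if c.points["sd"].notna().any():
            lo = c.points["expected_richness"] - c.points["sd"]
            hi = c.points["expected_richness"] + c.points["sd"]
            ax.fill_between(c.points["t"], lo, hi, alpha=0.2)
    ax.set_xlabel("samples")
    ax.set_ylabel("expected species richness")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rank_abundance_plot(ras: dict[str, RankAbundance], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, ra in ras.items():
        ax.semilogy(ra.table["rank"], ra.table["relative_abundance"],
                    marker="o", label=label)
    ax.set_xlabel("species rank")
    ax.set_ylabel("relative abundance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bipartite_web_plot(m: InteractionMatrix, taxa: Sequence[PlantTaxon],
                       species: Sequence[FlySpecies], path: str | Path) -> None:
    """Hosts left, flies right; neotropical nodes black, exotic grey."""
    host_origin = {t.code: t.origin.value for t in taxa}
    fly_origin = {s.code: s.origin.value for s in species}
    hosts = [c for c in m.counts.columns if m.counts[c].sum() > 0]
    flies = [c for c in m.counts.index if m.counts.loc[c].sum() > 0]
    hy = {c: i / max(1, len(hosts) - 1) for i, c in enumerate(hosts)}
    fy = {c: i / max(1, len(flies) - 1) for i, c in enumerate(flies)}
    total = m.counts.to_numpy().sum() or 1

    fig, ax = plt.subplots(figsize=(6, max(4, len(hosts) * 0.18)))
    for f in flies:
        for h in hosts:
            c = m.counts.loc[f, h]
            if c >= 1:
                ax.plot([0, 1], [hy[h], fy[f]], color="k",
                        lw=0.5 + 4.0 * c / total, alpha=0.5)
    for c in hosts:
        ax.plot(0, hy[c], "s", color="k" if host_origin[c] == "N" else "0.6", ms=6)
        ax.annotate(c, (0, hy[c]), xytext=(-8, 0), textcoords="offset points",
                    ha="right", va="center", fontsize=6)
    for c in flies:
        ax.plot(1, fy[c], "o", color="k" if fly_origin[c] == "N" else "0.6", ms=6)
        ax.annotate(c, (1, fy[c]), xytext=(8, 0), textcoords="offset points",
                    ha="left", va="center", fontsize=6)
    ax.set_xlim(-0.25, 1.25)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
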