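"""Figure helpers: metagene profiles and group boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .metagene import MetageneProfile  # noqa: E402


def plot_metagene(profile: MetageneProfile, path=None, title: str | None = None):
    """Tier-coloured line plot over upstream flank / body / downstream flank."""
    B = profile.n_bins
    fig, ax = plt.subplots(figsize=(6, 4))
    for tier in profile.values.index:
        ax.plot(range(3 * B), profile.values.loc[tier], label=str(tier))
    for x in (B, 2 * B):
        ax.axvline(x, color="grey", lw=0.6, ls="--")
    ax.set_xticks([0, B, 2 * B, 3 * B - 1])
    ax.set_xticklabels([f"-{profile.flank_bp // 1000} kb", "TSS", "TES",
                        f"+{profile.flank_bp // 1000} kb"])
    ax.set_ylabel("density (RPK10M)")
    ax.legend(title="expression tier", frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_group_boxes(values_by_group: dict, path=None, ylabel: str = "density (RPK10M)"):
    """Boxplot of a signal split by group (e.g. most vs least reduced)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    labels = list(values_by_group)
    ax.boxplot([values_by_group[k] for k in labels], tick_labels=labels, showfliers=False)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
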