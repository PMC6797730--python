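"""Optional plotting helpers (bias profile and saturation curve)."""

from __future__ import annotations

from typing import Sequence


def plot_bias_profiles(profiles: Sequence, path: str) -> None:
    """Mean relative coverage vs signed offset with SE error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for profile in profiles:
        if not profile.defined:
            continue
        ax.errorbar(
            profile.positions, profile.means, yerr=profile.stderrs,
            marker="o", capsize=3,
            label=f"{profile.bin_label} (n={profile.n_transcripts})",
        )
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("position relative to internal run (nt)")
    ax.set_ylabel("mean relative coverage")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_saturation(curve, path: str) -> None:
    """Distinct transcripts vs subsampled depth (log-x)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(curve["depth"], curve["mean_distinct"], yerr=curve["sd_distinct"],
                marker="o", capsize=3)
    ax.set_xscale("log")
    ax.set_xlabel("subsampled reads")
    ax.set_ylabel("distinct transcripts detected")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
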