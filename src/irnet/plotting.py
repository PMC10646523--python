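"""Optional PNG rendering of recurrence plots and lead-lag profiles.

Requires matplotlib (the ``plot`` extra); imports are deferred so the rest
of the package works without it.
"""

from __future__ import annotations

__all__ = ["plot_recurrence", "plot_dcrp"]


def plot_recurrence(rp, path, title: str | None = None) -> None:
    """Render a (cross-)recurrence matrix as a black-on-white PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rp.matrix, cmap="binary", origin="lower", interpolation="none")
    ax.set_xlabel("j")
    ax.set_ylabel("i")
    ax.set_title(title or f"{rp.kind} recurrence plot (RR={rp.realized_rr:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dcrp(profile, path, title: str | None = None) -> None:
    """Diagonal cross-recurrence profile with its surrogate envelope."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    if profile.surrogate_lo is not None:
        ax.fill_between(
            profile.lags,
            profile.surrogate_lo,
            profile.surrogate_hi,
            color="0.8",
            label=f"{profile.n_surrogates}-surrogate envelope",
        )
    ax.plot(profile.lags, profile.rate, color="k", lw=1.5, label="observed")
    ax.axvline(0, color="0.5", lw=0.5)
    ax.set_xlabel("lag (negative: X leads)")
    ax.set_ylabel("recurrence rate")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
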