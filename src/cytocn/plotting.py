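"""Basic per-chromosome CN/BAF panels (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .segmentation import MarkerTrack, Segment, paired_cn  # noqa: E402

__all__ = ["plot_pair"]


def plot_pair(tumor: MarkerTrack, normal: MarkerTrack, chrom: int,
              segments: list[Segment] | None = None, path=None):
    """Two-panel figure (CN on a linear scale, tumor BAF) for one chromosome."""
    mask = tumor.chrom == chrom
    pos = tumor.pos[mask] / 1e6
    cn = paired_cn(tumor, normal)[mask]
    fig, (ax_cn, ax_baf) = plt.subplots(2, 1, sharex=True, figsize=(9, 4.5))
    ax_cn.plot(pos, cn, ".", ms=2, color="0.4")
    ax_cn.axhline(2.0, color="k", lw=0.5)
    for thr, c in ((2.5, "red"), (1.5, "blue")):
        ax_cn.axhline(thr, color=c, lw=0.5, ls="--")
    if segments:
        for s in segments:
            if s.chrom == chrom:
                ax_cn.hlines(s.geo_mean_cn, s.start / 1e6, s.end / 1e6,
                             color="orange", lw=2)
    ax_cn.set_ylabel("CN")
    ax_cn.set_ylim(0, 4.5)
    ax_baf.plot(pos, tumor.baf[mask], ".", ms=2, color="0.4")
    ax_baf.set_ylabel("BAF")
    ax_baf.set_ylim(-0.02, 1.02)
    ax_baf.set_xlabel(f"chr{chrom} position (Mb)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
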