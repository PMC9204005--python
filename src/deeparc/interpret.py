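"""Attention-weight interpretation: averaged profiles, peak localization,
and heatmap export.

Attention positions index k-mer tokens; token i covers bases [i, i+k)
(0-based, half-open), so for small k a token index is directly comparable to
the base coordinate where an implanted motif starts.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from .sequences import LabeledSequenceSet


@dataclasses.dataclass
class AttentionProfile:
    """Per-position attention weights, single-window or dataset-averaged.

    An average of per-window distributions is itself a distribution (each
    window's weights sum to 1), so ``weights`` always sums to 1.
    """

    weights: np.ndarray
    k: int = 3
    n_windows: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError(f"profile weights must be 1-D, got shape {w.shape}")
        if (w < -1e-9).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("profile weights must form a distribution (sum 1, >= 0)")
        self.weights = w

    def base_interval(self, position: int) -> tuple[int, int]:
        """Base coordinates [start, end) covered by k-mer position ``position``."""
        return position, position + self.k


def collect_attention(model, data, positives_only: bool = True,
                      return_matrix: bool = False):
    """Dataset-averaged attention profile from a fitted attention-bearing model.

    ``data`` is a LabeledSequenceSet (or list of window strings). By default
    only label-1 windows are averaged, since negatives carry no motif;
    ``positives_only=False`` averages every window.
    """
    if isinstance(data, LabeledSequenceSet):
        records = [r for r in data if r.label == 1] if positives_only else list(data)
        seqs = [r.sequence for r in records]
    else:
        seqs = list(data)
    if not seqs:
        raise ValueError("no windows to collect attention from")
    alphas = model.attention(seqs)  # raises for non-attention architectures
    profile = AttentionProfile(alphas.mean(axis=0), k=getattr(model, "k", 3),
                               n_windows=len(seqs))
    if return_matrix:
        return profile, alphas
    return profile


def locate_peaks(profile: AttentionProfile, max_peaks: int = 1,
                 min_separation: int = 10) -> list[int]:
    """Up to ``max_peaks`` local maxima, greedy by height with neighbourhood
    suppression; ties resolve to the leftmost position."""
    if max_peaks < 1 or min_separation < 0:
        raise ValueError("max_peaks must be >= 1 and min_separation >= 0")
    w = profile.weights.copy()
    peaks: list[int] = []
    for _ in range(max_peaks):
        if not np.isfinite(w).any():
            break
        i = int(np.nanargmax(w))  # argmax returns the first (leftmost) maximum
        if np.isneginf(w[i]):
            break
        peaks.append(i)
        lo = max(0, i - min_separation)
        w[lo:i + min_separation + 1] = -np.inf
    return peaks


def export_heatmap(profiles: list[AttentionProfile], path: str | Path,
                   row_names: list[str] | None = None,
                   render_image: bool = True) -> Path:
    """Write profiles as a TSV matrix (rows = profiles, cols = positions) and,
    when matplotlib is usable, a PNG heatmap next to it.

    The TSV is the artifact of record; a failed render degrades to TSV-only
    with a warning.
    """
    if not profiles:
        raise ValueError("no profiles to export")
    lengths = {len(p.weights) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have mixed lengths {sorted(lengths)}")
    path = Path(path)
    names = row_names or [f"profile_{i}" for i in range(len(profiles))]
    if len(names) != len(profiles):
        raise ValueError("row_names length must match profiles")
    T = lengths.pop()
    with open(path, "w") as fh:
        fh.write("profile\t" + "\t".join(f"pos_{j}" for j in range(T)) + "\n")
        for name, p in zip(names, profiles):
            fh.write(name + "\t" + "\t".join(repr(float(x)) for x in p.weights) + "\n")

    if render_image:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(8, 1 + 0.5 * len(profiles)))
            im = ax.imshow(np.vstack([p.weights for p in profiles]),
                           aspect="auto", cmap="viridis")
            ax.set_yticks(range(len(names)), names)
            ax.set_xlabel("k-mer position")
            fig.colorbar(im, ax=ax, label="mean attention weight")
            fig.tight_layout()
            fig.savefig(path.with_suffix(".png"), dpi=120)
            plt.close(fig)
        except Exception as exc:  # rendering is best-effort
            warnings.warn(f"heatmap rendering failed ({exc}); TSV written", RuntimeWarning)
    return path


def read_heatmap_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Round-trip reader for :func:`export_heatmap` TSVs."""
    names, rows = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return names, np.array(rows)
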