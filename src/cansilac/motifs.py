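"""Position-specific sequence motif enrichment around Arg/canavanine sites.

Windows of five residues on each side of a site are compared between a
foreground (canavanine sites) and a background (all Arg/canavanine
sites) with an iterative greedy search in the style of motif-x: at each
step the (position, residue) pair with the smallest binomial tail
probability — foreground count given the background frequency — is fixed
if it passes the significance threshold and minimum support, both window
sets are filtered to matching windows, and the search recurses.  Each
completed pattern is emitted, its matching foreground windows are
removed, and the search restarts until nothing passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PAD",
    "SequenceWindow",
    "MotifResult",
    "extract_windows",
    "motif_discovery",
]

#: Padding character for positions that fall off the protein ends.
PAD = "-"

#: Alphabet considered at each window position.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-width window centered on an Arg/canavanine site."""

    text: str
    half_width: int = 5

    def __post_init__(self) -> None:
        if len(self.text) != 2 * self.half_width + 1:
            raise ValueError(
                f"window {self.text!r} has length {len(self.text)}, "
                f"expected {2 * self.half_width + 1}"
            )

    @property
    def center(self) -> str:
        return self.text[self.half_width]


@dataclass(frozen=True)
class MotifResult:
    """One discovered motif: fixed positions, per-step p-values, support."""

    pattern: tuple[tuple[int, str], ...]  # (offset from center, residue)
    step_p_values: tuple[float, ...]
    support: int
    fold_enrichment: float

    def pattern_string(self, half_width: int = 5, center: str = "R") -> str:
        chars = ["."] * (2 * half_width + 1)
        chars[half_width] = center
        for offset, residue in self.pattern:
            chars[half_width + offset] = residue
        return "".join(chars)


def extract_windows(
    sites: Sequence[tuple[str, int]],
    proteins: Mapping[str, str],
    half_width: int = 5,
) -> list[SequenceWindow]:
    """Windows of ``half_width`` residues on each side of each site.

    ``sites`` are (protein id, 1-based position) pairs; positions
    falling off a protein terminus are padded with ``'-'``.
    """
    windows = []
    for protein_id, position in sites:
        try:
            seq = proteins[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id: {protein_id!r}") from None
        if not (1 <= position <= len(seq)):
            raise ValueError(
                f"position {position} out of range for protein "
                f"{protein_id!r} of length {len(seq)}"
            )
        i = position - 1
        chars = []
        for j in range(i - half_width, i + half_width + 1):
            chars.append(seq[j] if 0 <= j < len(seq) else PAD)
        windows.append(SequenceWindow("".join(chars), half_width))
    return windows


def _to_matrix(windows: Sequence[SequenceWindow]) -> np.ndarray:
    return np.array([list(w.text) for w in windows])


def _best_candidate(
    fg: np.ndarray,
    bg: np.ndarray,
    fixed: set[int],
    half_width: int,
    p_threshold: float,
    min_support: int,
) -> tuple[float, int, str, int] | None:
    """Smallest-p (position, residue) candidate passing the thresholds.

    Padding characters are excluded from both the numerator and the
    denominator of position frequencies.  Ties break by smallest p, then
    leftmost position, then alphabetical residue — the iteration order
    below enforces this deterministically.
    """
    width = 2 * half_width + 1
    best: tuple[float, int, str, int] | None = None
    for col in range(width):
        if col == half_width or col in fixed:
            continue
        fg_col = fg[:, col]
        bg_col = bg[:, col]
        fg_valid = fg_col != PAD
        bg_valid = bg_col != PAD
        n = int(fg_valid.sum())
        n_bg = int(bg_valid.sum())
        if n == 0 or n_bg == 0:
            continue
        for residue in RESIDUES:
            k = int((fg_col == residue).sum())
            if k < min_support:
                continue
            p_bg = float((bg_col == residue).sum()) / n_bg
            if p_bg == 0.0:
                p_bg = 1.0 / (n_bg + 1)  # unseen in background: pseudo-count
            p = float(stats.binom.sf(k - 1, n, p_bg))
            if p >= p_threshold:
                continue
            if best is None or (p, col, residue) < (best[0], best[1], best[2]):
                best = (p, col, residue, k)
    return best


def motif_discovery(
    foreground: Sequence[SequenceWindow],
    background: Sequence[SequenceWindow],
    p_threshold: float = 1e-6,
    min_support: int = 20,
) -> list[MotifResult]:
    """Iterative greedy discovery of enriched position-specific motifs.

    Returns the (possibly empty) list of motifs; an empty list is the
    valid "no enriched motif" outcome.
    """
    if len(foreground) == 0 or len(background) == 0:
        raise ValueError("foreground and background must be non-empty")
    half_width = foreground[0].half_width
    fg_all = _to_matrix(foreground)
    bg_all = _to_matrix(background)
    results: list[MotifResult] = []

    while fg_all.shape[0] > 0 and bg_all.shape[0] > 0:
        fg = fg_all
        bg = bg_all
        fixed: dict[int, str] = {}
        p_values: list[float] = []
        while True:
            cand = _best_candidate(
                fg, bg, set(fixed), half_width, p_threshold, min_support
            )
            if cand is None:
                break
            p, col, residue, _ = cand
            fixed[col] = residue
            p_values.append(p)
            fg = fg[fg[:, col] == residue]
            bg = bg[bg[:, col] == residue]
        if not fixed:
            break
        support = fg.shape[0]
        # fold enrichment of the complete pattern vs the original sets
        fg_frac = support / fg_all.shape[0]
        bg_match = np.ones(bg_all.shape[0], dtype=bool)
        fg_match = np.ones(fg_all.shape[0], dtype=bool)
        for col, residue in fixed.items():
            bg_match &= bg_all[:, col] == residue
            fg_match &= fg_all[:, col] == residue
        bg_frac = bg_match.sum() / bg_all.shape[0] if bg_all.shape[0] else float("nan")
        fold = fg_frac / bg_frac if bg_frac > 0 else float("inf")
        pattern = tuple(
            sorted((col - half_width, residue) for col, residue in fixed.items())
        )
        results.append(
            MotifResult(
                pattern=pattern,
                step_p_values=tuple(p_values),
                support=support,
                fold_enrichment=float(fold),
            )
        )
        fg_all = fg_all[~fg_match]
        bg_all = bg_all[~bg_match]
    return results
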