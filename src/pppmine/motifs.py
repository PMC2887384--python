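"""Gapless position-weight motif models.

Short, ungapped sequence motifs (such as the ~13-residue stretch leading
into a double-glycine cleavage site) are modelled as position-weight
matrices: per-position residue probabilities estimated from a gapless
alignment with pseudocount smoothing, scored in bits as log2 odds against
a background distribution.  A window scoring above 0 bits is more likely
under the motif than under the background.  Models can emit a consensus
(per-position argmax) sequence and be searched across whole proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np

from .datamodel import AA_ALPHABET, ProteinRecord, ValidationError

PathLike = Union[str, Path]

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


class WindowScore(NamedTuple):
    offset: int
    bits: float


@dataclass(frozen=True)
class ScanResult:
    best: Optional[WindowScore]
    above_threshold: tuple
    too_short: bool = False


@dataclass(frozen=True)
class GaplessMotifModel:
    """Fixed-length log-odds motif model over the 20-residue alphabet.

    Attributes
    ----------
    probabilities : ndarray, shape (L, 20)
        Pseudocount-smoothed per-position residue probabilities; each row
        sums to 1.
    background : ndarray, shape (20,)
        Background residue frequencies.
    log_odds : ndarray, shape (L, 20)
        ``log2(probabilities / background)`` in bits.
    """

    motif_id: str
    probabilities: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 20:
            raise ValidationError("probabilities must have shape (L, 20)")
        if bg.shape != (20,):
            raise ValidationError("background must have shape (20,)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("per-position probabilities must sum to 1")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background)

    # -- scoring ----------------------------------------------------------

    def score_window(self, sequence: str, offset: int) -> float:
        """Bit score of the length-L window starting at ``offset``.

        Residues outside the 20-letter alphabet (e.g. ``X``) contribute the
        background-neutral value of 0 bits.
        """
        if offset < 0 or offset + self.length > len(sequence):
            raise ValidationError(
                f"window [{offset}, {offset + self.length}) out of range "
                f"for sequence of length {len(sequence)}"
            )
        lo = self.log_odds
        total = 0.0
        for pos in range(self.length):
            idx = _AA_INDEX.get(sequence[offset + pos])
            if idx is not None:
                total += lo[pos, idx]
        return total

    def scan_sequence(self, sequence: str, threshold_bits: float = 0.0) -> ScanResult:
        """Score every window; report the best (smallest offset on ties)
        and all windows above the threshold."""
        if len(sequence) < self.length:
            return ScanResult(best=None, above_threshold=(), too_short=True)
        scores = [
            WindowScore(off, self.score_window(sequence, off))
            for off in range(len(sequence) - self.length + 1)
        ]
        best = max(scores, key=lambda w: (w.bits, -w.offset))
        above = tuple(w for w in scores if w.bits > threshold_bits)
        return ScanResult(best=best, above_threshold=above)

    def emit_consensus(self) -> str:
        """Per-position argmax residue; ties resolve to the alphabetically
        first residue (the alphabet is stored sorted, so argmax suffices)."""
        return "".join(AA_ALPHABET[i] for i in np.argmax(self.probabilities, axis=1))

    def max_score(self) -> float:
        return float(np.max(self.log_odds, axis=1).sum())


def build_motif(
    aligned_sequences: Sequence[str],
    background: Optional[Mapping[str, float]] = None,
    pseudocount: float = 0.5,
    motif_id: str = "motif",
) -> GaplessMotifModel:
    """Estimate a motif model from a gapless alignment.

    Per position, ``P(aa) = (count + alpha) / (N_valid + 20 alpha)`` where
    ``N_valid`` counts alignment rows with a standard residue at that
    position (``X`` is ignored).  ``alpha = 0`` is allowed for
    exact-identity uses but requires every residue column to be observed.
    """
    seqs = list(aligned_sequences)
    if not seqs:
        raise ValidationError("build_motif requires at least one sequence")
    L = len(seqs[0])
    if L < 2:
        raise ValidationError("motif length must be >= 2")
    if any(len(s) != L for s in seqs):
        raise ValidationError("aligned sequences must all share one length")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    bg = _background_vector(background)
    counts = np.zeros((L, 20), dtype=float)
    valid = np.zeros(L, dtype=float)
    for s in seqs:
        for pos, aa in enumerate(s):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                counts[pos, idx] += 1
                valid[pos] += 1
    if pseudocount == 0 and np.any(valid == 0):
        raise ValidationError("zero pseudocount with an all-X column")
    probs = (counts + pseudocount) / (valid + 20 * pseudocount)[:, None]
    return GaplessMotifModel(motif_id=motif_id, probabilities=probs, background=bg)


def _background_vector(background: Optional[Mapping[str, float]]) -> np.ndarray:
    if background is None:
        return np.full(20, 0.05)
    vec = np.array([background.get(aa, 0.0) for aa in AA_ALPHABET], dtype=float)
    if abs(vec.sum() - 1.0) > 1e-6:
        raise ValidationError(f"background frequencies sum to {vec.sum()}, expected 1")
    if np.any(vec <= 0):
        raise ValidationError("background frequencies must be strictly positive")
    return vec


def cross_family_search(
    model: GaplessMotifModel,
    proteome_records: Iterable[ProteinRecord],
    top_n: int = 25,
) -> list[tuple[str, WindowScore]]:
    """Rank proteins by their best-window bit score against the model.

    Proteins shorter than the model are skipped.  Returns at most ``top_n``
    (protein_id, best window) pairs by descending bits, ties by protein_id,
    independent of input record order.
    """
    scored = []
    for rec in proteome_records:
        result = model.scan_sequence(rec.sequence)
        if result.best is not None:
            scored.append((rec.protein_id, result.best))
    scored.sort(key=lambda t: (-t[1].bits, t[0]))
    return scored[:top_n]


# ---------------------------------------------------------------------------
# Serialization: MEME-like plain-text matrix
# ---------------------------------------------------------------------------

def write_motif(model: GaplessMotifModel, path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write(f"MOTIF {model.motif_id}\n")
        handle.write("ALPHABET " + AA_ALPHABET + "\n")
        handle.write(
            "BACKGROUND " + " ".join(f"{v:.12g}" for v in model.background) + "\n"
        )
        handle.write(f"MATRIX length {model.length}\n")
        for row in model.probabilities:
            handle.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_motif(path: PathLike) -> GaplessMotifModel:
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    if not lines or not lines[0].startswith("MOTIF "):
        raise ValidationError(f"{path}: not a motif file")
    motif_id = lines[0].split(" ", 1)[1]
    if lines[1] != "ALPHABET " + AA_ALPHABET:
        raise ValidationError(f"{path}: unexpected alphabet line")
    background = np.array([float(v) for v in lines[2].split()[1:]], dtype=float)
    length = int(lines[3].split()[-1])
    probs = np.array(
        [[float(v) for v in lines[4 + i].split()] for i in range(length)],
        dtype=float,
    )
    return GaplessMotifModel(motif_id=motif_id, probabilities=probs, background=background)
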