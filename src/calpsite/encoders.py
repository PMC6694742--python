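"""Feature encoders for peptide windows: AAC, binary, positional frequency profile, CKSAAP.

All four encoders share the fixed 21-symbol alphabet ``ACDEFGHIKLMNPQRSTVWY-``
(the 20 standard residues followed by the terminal pad).  For a window of
length ``W`` (30 at the default flank of 15) and maximum pair spacing
``kmax`` the output lengths are:

==============  =======================  =====================
encoder         length                   at W=30, kmax=3
==============  =======================  =====================
AAC             21                       21
binary (BE)     21·W                     630
PSFM            2·W                      60
CKSAAP          441·(kmax+1)             1764
==============  =======================  =====================
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import LabeledDataset, PAD, STANDARD_RESIDUES

#: Fixed encoder alphabet: A first, the pad symbol last.
ALPHABET = STANDARD_RESIDUES + PAD
N_SYMBOLS = len(ALPHABET)  # 21
N_PAIRS = N_SYMBOLS * N_SYMBOLS  # 441

_SYMBOL_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def _window_indices(window: str) -> np.ndarray:
    try:
        return np.array([_SYMBOL_INDEX[c] for c in window], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} outside encoder alphabet") from exc


def encode_aac(window: str) -> np.ndarray:
    """Amino-acid composition: per-symbol frequency over the window (length 21, sums to 1)."""
    idx = _window_indices(window)
    counts = np.bincount(idx, minlength=N_SYMBOLS).astype(float)
    return counts / len(window)


def encode_binary(window: str) -> np.ndarray:
    """Concatenated one-hot encoding, one 21-block per window position (length 21·W)."""
    idx = _window_indices(window)
    out = np.zeros((len(window), N_SYMBOLS))
    out[np.arange(len(window)), idx] = 1.0
    return out.ravel()


def decode_binary(vector: np.ndarray) -> str:
    """Invert :func:`encode_binary` by per-block argmax."""
    blocks = np.asarray(vector).reshape(-1, N_SYMBOLS)
    return "".join(ALPHABET[i] for i in blocks.argmax(axis=1))


@dataclass
class FrequencyProfile:
    """Per-position symbol frequencies of positive and negative training windows.

    ``pos_freq[j, s]`` is the fraction of positive training windows carrying
    alphabet symbol ``s`` at window position ``j`` (0-based); ``neg_freq`` is
    the negative-class analogue.  Each row sums to 1.  This is a plain
    occurrence-frequency profile fit on the training data, not a log-odds
    substitution matrix.
    """

    pos_freq: np.ndarray
    neg_freq: np.ndarray

    def __post_init__(self) -> None:
        self.pos_freq = np.asarray(self.pos_freq, dtype=float)
        self.neg_freq = np.asarray(self.neg_freq, dtype=float)
        if self.pos_freq.shape != self.neg_freq.shape:
            raise ValueError("pos_freq and neg_freq shapes differ")
        if self.pos_freq.ndim != 2 or self.pos_freq.shape[1] != N_SYMBOLS:
            raise ValueError(f"profile must have {N_SYMBOLS} columns")

    @property
    def window_length(self) -> int:
        return self.pos_freq.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        W = self.window_length
        with open(path, "w") as fh:
            cols = [f"pos_{c}" for c in ALPHABET] + [f"neg_{c}" for c in ALPHABET]
            fh.write("position\t" + "\t".join(cols) + "\n")
            for j in range(W):
                row = np.concatenate([self.pos_freq[j], self.neg_freq[j]])
                fh.write(
                    str(j + 1) + "\t" + "\t".join(repr(float(x)) for x in row) + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyProfile":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["position"] + [f"pos_{c}" for c in ALPHABET] + [
                f"neg_{c}" for c in ALPHABET
            ]
            if header != expected:
                raise ValueError(f"{path}: unexpected profile header")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in fields[1:]])
        mat = np.asarray(rows)
        return cls(mat[:, :N_SYMBOLS], mat[:, N_SYMBOLS:])


def fit_frequency_profile(
    dataset: LabeledDataset, smoothing: float = 0.0
) -> FrequencyProfile:
    """Fit per-position symbol frequencies separately on positive and negative windows.

    ``smoothing`` adds an optional additive (Laplace) pseudocount per symbol;
    the default of 0 keeps plain occurrence frequencies, so unseen symbols get
    frequency 0.
    """
    if dataset.n_positive == 0 or dataset.n_negative == 0:
        raise ValueError("profile requires at least one window of each class")
    W = len(dataset.windows[0])
    freqs = []
    for label in (1, 0):
        counts = np.full((W, N_SYMBOLS), smoothing, dtype=float)
        for win, lab in zip(dataset.windows, dataset.labels):
            if lab != label:
                continue
            if len(win) != W:
                raise ValueError("inconsistent window lengths in dataset")
            counts[np.arange(W), _window_indices(win)] += 1.0
        freqs.append(counts / counts.sum(axis=1, keepdims=True))
    return FrequencyProfile(pos_freq=freqs[0], neg_freq=freqs[1])


def encode_psfm(window: str, profile: FrequencyProfile) -> np.ndarray:
    """Profile lookup: positive-class then negative-class per-position frequencies (length 2·W)."""
    if len(window) != profile.window_length:
        raise ValueError(
            f"window length {len(window)} does not match profile length "
            f"{profile.window_length}"
        )
    idx = _window_indices(window)
    j = np.arange(len(window))
    return np.concatenate([profile.pos_freq[j, idx], profile.neg_freq[j, idx]])


def encode_cksaap(window: str, kmax: int = 3) -> np.ndarray:
    """Composition of k-spaced symbol pairs for k = 0..kmax (length 441·(kmax+1)).

    For spacing ``k``, the count of ordered pairs ``(window[i], window[i+k+1])``
    is tallied per pair type; the per-k 441-blocks are concatenated in
    increasing k, pairs in row-major alphabet order.  Values are raw counts.
    """
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    if kmax >= len(window) - 1:
        raise ValueError(
            f"kmax {kmax} leaves no pair slot in a window of length {len(window)}"
        )
    idx = _window_indices(window)
    out = np.zeros((kmax + 1) * N_PAIRS, dtype=float)
    for k in range(kmax + 1):
        left = idx[: len(idx) - k - 1]
        right = idx[k + 1 :]
        pair_ids = left * N_SYMBOLS + right
        out[k * N_PAIRS : (k + 1) * N_PAIRS] = np.bincount(
            pair_ids, minlength=N_PAIRS
        )
    return out


@dataclass
class FeatureBundle:
    """The four encoder outputs for one window."""

    aac: np.ndarray
    be: np.ndarray
    psfm: np.ndarray
    cksaap: np.ndarray

    def as_list(self) -> list[np.ndarray]:
        return [self.aac, self.be, self.psfm, self.cksaap]


def encode_all(window: str, profile: FrequencyProfile, kmax: int = 3) -> FeatureBundle:
    """Apply all four encoders to one window; deterministic."""
    return FeatureBundle(
        aac=encode_aac(window),
        be=encode_binary(window),
        psfm=encode_psfm(window, profile),
        cksaap=encode_cksaap(window, kmax),
    )


def encode_windows(
    windows: list[str], profile: FrequencyProfile, kmax: int = 3
) -> list[np.ndarray]:
    """Batch-encode windows into the four feature matrices (one row per window)."""
    bundles = [encode_all(w, profile, kmax) for w in windows]
    return [
        np.stack([getattr(b, name) for b in bundles])
        for name in ("aac", "be", "psfm", "cksaap")
    ]


def feature_dims(flank: int = 15, kmax: int = 3) -> tuple[int, int, int, int]:
    """Input dimensions (AAC, BE, PSFM, CKSAAP) for a given flank and kmax."""
    W = 2 * flank
    return (N_SYMBOLS, N_SYMBOLS * W, 2 * W, N_PAIRS * (kmax + 1))
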