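"""Window extraction and profile-bigram feature vectors.

Each lysine is described by the 31-residue segment centered on it (15
residues up- and downstream). Where the segment runs past a protein
terminus the missing stretch is filled by mirroring the profile rows about
the terminal residue. The two windowed profiles — a 31x20 PSSM slice and a
31x3 secondary-structure slice — are then condensed into bigram matrices:

    B[p, q]  = sum_k  M[k, p] * M[k+1, q]      (20 x 20, PSSM)
    B'[r, s] = sum_k  N[k, r] * N[k+1, s]      (3 x 3, secondary structure)

summing over the 30 consecutive row pairs of the window. Row-major
flattening and concatenation give the 409-dimensional feature vector
(400 PSSM-bigram + 9 SS-bigram transitional probabilities). The dimension
is independent of the window size, so the flank is a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ProteinProfile, SiteRecord

FLANK_DEFAULT = 15
N_FEATURES = 409


@dataclass
class WindowPair:
    """The two profile windows centered on one annotated lysine."""

    site: SiteRecord
    pssm_window: np.ndarray  # (2*flank+1, 20)
    ss_window: np.ndarray    # (2*flank+1, 3)


def mirror_indices(position: int, flank: int, length: int) -> np.ndarray:
    """Row indices of the window, reflecting out-of-range indices.

    An index j < 0 maps to -j and j >= L to 2(L-1) - j, applied repeatedly
    (ping-pong) until in range, i.e. reflection about the terminal residue
    without duplicating it.
    """
    if length < 2:
        raise ValueError("protein too short to mirror (L < 2)")
    idx = np.arange(position - flank, position + flank + 1)
    period = 2 * (length - 1)
    idx = np.abs(idx) % period
    idx = np.where(idx >= length, period - idx, idx)
    return idx


def extract_window(profile: ProteinProfile, position: int,
                   flank: int = FLANK_DEFAULT,
                   site: SiteRecord | None = None) -> WindowPair:
    """Slice the two profiles around ``position`` (0-based), mirroring at
    the termini. Both windows use the same index map."""
    if not (0 <= position < profile.length):
        raise ValueError(
            f"{profile.protein_id}: position {position} outside protein "
            f"of length {profile.length}"
        )
    idx = mirror_indices(position, flank, profile.length)
    if site is None:
        site = SiteRecord(profile.protein_id, position, 0)
    return WindowPair(site, profile.pssm[idx], profile.sspre[idx])


def bigram(window: np.ndarray) -> np.ndarray:
    """Profile-bigram transform of a (W, C) window into a (C, C) matrix.

    ``out[p, q] = sum_{k=0}^{W-2} window[k, p] * window[k+1, q]`` — the sum
    of outer products of the W-1 consecutive row pairs.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 2:
        raise ValueError("window must be 2-D with at least 2 rows")
    return window[:-1].T @ window[1:]


def feature_vector(pair: WindowPair) -> np.ndarray:
    """409-entry feature vector: row-major flattened 20x20 PSSM bigram
    followed by the row-major flattened 3x3 SS bigram."""
    return np.concatenate([
        bigram(pair.pssm_window).ravel(),
        bigram(pair.ss_window).ravel(),
    ])


def featurize_dataset(profiles: dict[str, ProteinProfile],
                      sites: Sequence[SiteRecord],
                      flank: int = FLANK_DEFAULT,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n_sites, 409) and label vector, rows in site order."""
    X = np.empty((len(sites), N_FEATURES), dtype=float)
    y = np.empty(len(sites), dtype=int)
    for i, site in enumerate(sites):
        if site.protein_id not in profiles:
            raise KeyError(f"site {i}: unknown protein {site.protein_id!r}")
        try:
            pair = extract_window(profiles[site.protein_id], site.position,
                                  flank, site)
        except ValueError as exc:
            raise ValueError(
                f"site {i} ({site.protein_id}:{site.position + 1}): {exc}"
            ) from exc
        X[i] = feature_vector(pair)
        y[i] = site.label
    return X, y


def save_features_tsv(path, sites: Sequence[SiteRecord],
                      X: np.ndarray, y: np.ndarray) -> None:
    """One row per site: protein_id, 1-based position, label, f1..f409."""
    with open(path, "w") as fh:
        header = ["protein_id", "position", "label"] + [
            f"f{j + 1}" for j in range(X.shape[1])
        ]
        fh.write("\t".join(header) + "\n")
        for site, row, label in zip(sites, X, y):
            fields = [site.protein_id, str(site.position + 1), str(int(label))]
            fields += [f"{v:.10g}" for v in row]
            fh.write("\t".join(fields) + "\n")


def load_features_tsv(path) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    """Inverse of :func:`save_features_tsv`; returns (id, 1-based position)
    pairs, the feature matrix, and the labels."""
    ids: list[tuple[str, int]] = []
    rows: list[list[float]] = []
    labels: list[int] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id\t"):
            raise ValueError(f"{path}: not a feature TSV")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            ids.append((fields[0], int(fields[1])))
            labels.append(int(fields[2]))
            rows.append([float(v) for v in fields[3:]])
    return ids, np.array(rows, dtype=float), np.array(labels, dtype=int)
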