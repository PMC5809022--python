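"""Synthetic benchmark generator for the full prediction pipeline.

Real inputs to the predictor come from PSI-BLAST (PSSM) and SPIDER2
(secondary structure), run over curated succinylation data. This module
fabricates statistically controlled stand-ins for all four input families
— sequences with lysines, row-stochastic L x 20 and L x 3 profile
matrices, and site labels — so every downstream stage can be exercised
and validated without those external tools.

Profile rows are Dirichlet draws around the uniform simplex point with a
common concentration. Positive (succinylated) lysines carry a planted,
window-local signal: every profile row within ``flank`` residues of the
site is redrawn from a Dirichlet whose mean is shifted toward a fixed
amino-acid pair (alternating by residue parity, so consecutive rows form
a recognisable bigram transition) and toward the helix state, with the
shift proportional to the effect size ``delta``. At ``delta = 0`` the
two classes are identically distributed; the planted transition grows
monotonically with ``delta``, making the effect size directly
interpretable in bigram units.

Matrices are quantized at generation time to the resolution of the file
formats (integer percentages for the PSSM, three decimals for the
secondary structure), so in-memory profiles round-trip exactly through
the writers and readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .featurize import FLANK_DEFAULT, featurize_dataset
from .io import (ProteinProfile, SiteRecord, write_fasta, write_pssm,
                 write_sites, write_sspre)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_K_INDEX = AMINO_ACIDS.index("K")

# Planted signal targets: an A->D bigram transition in the PSSM
# (PSSM column order ARNDCQEGHILKMFPSTWYV) and helix in the SS profile.
_PSSM_BIAS_EVEN = 0   # column A
_PSSM_BIAS_ODD = 3    # column D
_SS_BIAS = 0          # helix column


@dataclass
class SynthConfig:
    """Generator settings.

    Defaults emulate desk-scale versions of the real inputs: a few dozen
    proteins of typical domain length, lysines at roughly proteome
    frequency, and a Dirichlet concentration producing moderately peaked
    profile rows as real predictors emit.
    """

    n_proteins: int = 40
    length_range: tuple[int, int] = (50, 150)
    lysine_rate: float = 0.06
    positive_rate: float = 0.5
    effect_size: float = 1.0
    concentration: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lysine_rate < 1):
            raise ValueError("lysine_rate must be in (0, 1)")
        if not (0 < self.positive_rate < 1):
            raise ValueError("positive_rate must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.length_range[0] < 2:
            raise ValueError("minimum length must be >= 2")


def _spaced_lysines(rng: np.random.Generator, length: int, rate: float,
                    min_gap: int) -> np.ndarray:
    """Lysine positions at roughly ``rate`` per residue, no two closer
    than ``min_gap``; greedy acceptance over a random permutation."""
    n_target = int(rng.binomial(length, rate))
    accepted: list[int] = []
    for pos in rng.permutation(length):
        if len(accepted) >= n_target:
            break
        if all(abs(pos - a) >= min_gap for a in accepted):
            accepted.append(int(pos))
    return np.sort(np.array(accepted, dtype=int))


def _biased_mean(n_cols: int, target: int, delta: float) -> np.ndarray:
    mean = np.full(n_cols, 1.0 / n_cols)
    mean[target] += delta
    return mean / mean.sum()


def _draw_rows(rng: np.random.Generator, n_rows: int, mean: np.ndarray,
               concentration: float) -> np.ndarray:
    alpha = np.maximum(concentration * mean.size * mean, 1e-3)
    return rng.dirichlet(alpha, size=n_rows)


def _quantize_pssm(rows: np.ndarray) -> np.ndarray:
    return np.round(rows * 100.0) / 100.0

def _quantize_ss(rows: np.ndarray) -> np.ndarray:
    return np.round(rows, 3)


def generate_dataset(config: SynthConfig, flank: int = FLANK_DEFAULT,
                     outdir: str | Path | None = None,
                     ) -> tuple[dict[str, ProteinProfile], list[SiteRecord]]:
    """Generate proteins, profiles and labeled lysine sites.

    Every lysine becomes a site; it is positive with probability
    ``config.positive_rate``, in which case the profile rows of its
    window are redrawn with the class bias. If ``outdir`` is given the
    FASTA, per-protein ``.pssm``/``.spd3`` files and ``sites.tsv`` are
    written there in the exact dialects the readers consume.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    n_digits = len(str(config.n_proteins))

    profiles: dict[str, ProteinProfile] = {}
    sites: list[SiteRecord] = []
    any_lysine = False
    for p in range(config.n_proteins):
        pid = f"synth{p + 1:0{n_digits}d}"
        L = int(rng.integers(lo, hi + 1))
        # lysines spaced > 2*flank apart so no site's window reaches into
        # another site's planted region; without this, dense lysines would
        # contaminate negative windows and confound the effect size
        k_positions = _spaced_lysines(rng, L, config.lysine_rate,
                                      2 * flank + 1)
        is_k = np.zeros(L, dtype=bool)
        is_k[k_positions] = True
        others = rng.integers(0, 19, size=L)
        seq_idx = np.where(
            is_k, _K_INDEX,
            np.where(others >= _K_INDEX, others + 1, others))
        seq = "".join(AMINO_ACIDS[i] for i in seq_idx)

        pssm = _draw_rows(rng, L, np.full(20, 1 / 20), config.concentration)
        sspre = _draw_rows(rng, L, np.full(3, 1 / 3), config.concentration)

        labels = (rng.random(k_positions.size) < config.positive_rate
                  ).astype(int)
        for pos, label in zip(k_positions, labels):
            if label == 1:
                _plant(rng, pssm, sspre, int(pos), flank,
                       config.effect_size, config.concentration)
            sites.append(SiteRecord(pid, int(pos), int(label)))
            any_lysine = True

        profiles[pid] = ProteinProfile(pid, seq, _quantize_pssm(pssm),
                                       _quantize_ss(sspre))

    if not any_lysine:
        raise ValueError(
            "configuration produced no lysines; increase lysine_rate, "
            "protein count or lengths"
        )

    if outdir is not None:
        write_dataset(Path(outdir), profiles, sites)
    return profiles, sites


def _plant(rng: np.random.Generator, pssm: np.ndarray, sspre: np.ndarray,
           pos: int, flank: int, delta: float, concentration: float) -> None:
    """Redraw the profile rows of the window around ``pos`` with the
    class-specific bias (in place)."""
    L = pssm.shape[0]
    lo = max(0, pos - flank)
    hi = min(L, pos + flank + 1)
    for i in range(lo, hi):
        target = _PSSM_BIAS_EVEN if i % 2 == 0 else _PSSM_BIAS_ODD
        pssm[i] = _draw_rows(rng, 1, _biased_mean(20, target, delta),
                             concentration)[0]
        sspre[i] = _draw_rows(rng, 1, _biased_mean(3, _SS_BIAS, delta),
                              concentration)[0]


def write_dataset(outdir: Path, profiles: dict[str, ProteinProfile],
                  sites: list[SiteRecord]) -> None:
    """Write FASTA + per-protein profile files + sites.tsv under outdir."""
    outdir = Path(outdir)
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    (outdir / "ss").mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "proteins.fasta",
                [(p.protein_id, p.sequence) for p in profiles.values()])
    for p in profiles.values():
        write_pssm(outdir / "pssm" / f"{p.protein_id}.pssm", p.sequence,
                   np.round(p.pssm * 100.0))
        write_sspre(outdir / "ss" / f"{p.protein_id}.spd3", p.sequence,
                    p.sspre)
    write_sites(outdir / "sites.tsv", sites)


def generate_imbalanced(config: SynthConfig,
                        neg_to_pos_ratio: float = 10.3,
                        flank: int = FLANK_DEFAULT,
                        outdir: str | Path | None = None,
                        ) -> tuple[dict[str, ProteinProfile], list[SiteRecord]]:
    """Generate a dataset whose negative:positive ratio approximates the
    benchmark imbalance (default 10.3:1, the ratio of 18,344 negative to
    1,782 positive lysines scaled to the generated size).

    ``config.positive_rate`` is overridden by the ratio.
    """
    if neg_to_pos_ratio < 1:
        raise ValueError("neg_to_pos_ratio must be >= 1")
    cfg = SynthConfig(
        n_proteins=config.n_proteins, length_range=config.length_range,
        lysine_rate=config.lysine_rate,
        positive_rate=1.0 / (1.0 + neg_to_pos_ratio),
        effect_size=config.effect_size,
        concentration=config.concentration, seed=config.seed)
    return generate_dataset(cfg, flank=flank, outdir=outdir)


def planted_signal_features(n_sites: int, effect_size: float, seed: int,
                            flank: int = FLANK_DEFAULT,
                            positive_rate: float = 0.5,
                            concentration: float = 8.0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: generate until ``n_sites`` labeled lysines exist,
    truncate, and featurize. Returns (X, y) ready for training."""
    n_proteins = 20
    while True:
        cfg = SynthConfig(n_proteins=n_proteins, positive_rate=positive_rate,
                          effect_size=effect_size,
                          concentration=concentration, seed=seed)
        profiles, sites = generate_dataset(cfg, flank=flank)
        if len(sites) >= n_sites:
            break
        n_proteins *= 2
    sites = sites[:n_sites]
    return featurize_dataset(profiles, sites, flank=flank)
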