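"""Readers and writers for the profile-based input formats.

Three file families feed the predictor:

* protein sequences in multi-record FASTA;
* per-protein PSI-BLAST ASCII PSSMs (``-out_ascii_pssm`` dialect), of which
  the percentage block — the normalized substitution-probability matrix —
  is consumed and rescaled to [0, 1];
* per-protein secondary-structure probability tables in the SPIDER2
  ``.spd3`` style, giving P(coil), P(strand), P(helix) per residue.

Site annotations (which lysines are succinylated) arrive as a three-column
TSV. Everything is validated into :class:`ProteinProfile` and
:class:`SiteRecord` instances; positions are 1-based in files and converted
to 0-based internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# Column order of the PSI-BLAST ASCII PSSM header.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

# Canonical secondary-structure column order used throughout the package.
SS_STATES = ("H", "E", "C")  # helix, strand, coil

#: Absolute tolerance on a secondary-structure row sum (predictor outputs
#: are rounded to a few decimals, so rows rarely sum to exactly 1).
SS_ROW_SUM_TOL = 0.02


class ProfileIOError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class ProteinProfile:
    """One protein's sequence together with its two per-residue profiles.

    Attributes
    ----------
    protein_id : str
        Identifier (first whitespace token of the FASTA header).
    sequence : str
        Upper-case amino-acid sequence (20-letter alphabet plus ``X``).
    pssm : ndarray of shape (L, 20)
        Substitution probabilities in [0, 1], columns ordered as
        :data:`PSSM_ALPHABET`.
    sspre : ndarray of shape (L, 3)
        Secondary-structure probabilities in [0, 1], columns ordered
        (helix, strand, coil); each row sums to 1 within
        :data:`SS_ROW_SUM_TOL`.
    """

    protein_id: str
    sequence: str
    pssm: np.ndarray
    sspre: np.ndarray

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.sspre = np.asarray(self.sspre, dtype=float)
        L = len(self.sequence)
        if L < 2:
            raise ProfileIOError(
                f"{self.protein_id}: sequence must have length >= 2, got {L}"
            )
        if self.pssm.shape != (L, 20):
            raise ProfileIOError(
                f"{self.protein_id}: pssm shape {self.pssm.shape} != ({L}, 20)"
            )
        if self.sspre.shape != (L, 3):
            raise ProfileIOError(
                f"{self.protein_id}: sspre shape {self.sspre.shape} != ({L}, 3)"
            )
        for name, mat in (("pssm", self.pssm), ("sspre", self.sspre)):
            if np.any(mat < 0) or np.any(mat > 1):
                raise ProfileIOError(
                    f"{self.protein_id}: {name} entries outside [0, 1]"
                )
        sums = self.sspre.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > SS_ROW_SUM_TOL)
        if bad.size:
            raise ProfileIOError(
                f"{self.protein_id}: sspre row {bad[0] + 1} sums to "
                f"{sums[bad[0]]:.4f}, outside 1 +/- {SS_ROW_SUM_TOL}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """A lysine residue with its succinylation label.

    ``position`` is 0-based internally; file formats use 1-based positions.
    """

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ProfileIOError(
                f"{self.protein_id}:{self.position + 1}: label must be 0 or 1"
            )


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Parse a multi-record FASTA file into ``(id, sequence)`` pairs.

    The record id is the first whitespace-delimited token of the header
    line; sequences are uppercased and line folding is undone. Duplicate
    ids and empty files are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is not None:
            records.append((current_id, "".join(chunks).upper()))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise ProfileIOError(f"{path}: empty FASTA header")
                if current_id in seen:
                    raise ProfileIOError(f"{path}: duplicate id {current_id!r}")
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise ProfileIOError(f"{path}: sequence before first header")
                chunks.append(line)
    flush()
    if not records:
        raise ProfileIOError(f"{path}: no records")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_pssm(path: str | os.PathLike) -> tuple[np.ndarray, str]:
    """Parse a PSI-BLAST ASCII PSSM into an (L, 20) probability matrix.

    Only the percentage block (columns 23-42 of each residue row) is used;
    it is divided by 100 to give substitution probabilities. Returns the
    matrix together with the residue letters of the rows, so callers can
    cross-check against the FASTA sequence.
    """
    rows: list[list[float]] = []
    letters: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4:
        raise ProfileIOError(f"{path}: truncated PSSM (expected 3 header lines "
                             "and at least one residue row)")
    expected_index = 1
    in_body = False
    for lineno, raw in enumerate(lines[3:], start=4):
        tokens = raw.split()
        if not tokens:
            if in_body:
                break  # blank line ends the matrix; statistics follow
            continue
        if not tokens[0].isdigit():
            if in_body:
                break
            raise ProfileIOError(f"{path}:{lineno}: expected residue row")
        if len(tokens) < 42:
            raise ProfileIOError(
                f"{path}:{lineno}: residue row has {len(tokens)} tokens, "
                "expected at least 42 (index, residue, 20 scores, 20 percentages)"
            )
        in_body = True
        idx = int(tokens[0])
        if idx != expected_index:
            raise ProfileIOError(
                f"{path}:{lineno}: residue index {idx}, expected {expected_index}"
            )
        expected_index += 1
        letters.append(tokens[1])
        try:
            perc = [float(t) for t in tokens[22:42]]
        except ValueError as exc:
            raise ProfileIOError(f"{path}:{lineno}: non-numeric field") from exc
        if any(p < 0 or p > 100 for p in perc):
            raise ProfileIOError(
                f"{path}:{lineno}: percentage outside [0, 100]"
            )
        rows.append([p / 100.0 for p in perc])
    if not rows:
        raise ProfileIOError(f"{path}: no residue rows found")
    return np.array(rows, dtype=float), "".join(letters)


def write_pssm(path: str | os.PathLike, sequence: str,
               percentages: np.ndarray) -> None:
    """Emit an ASCII PSSM in the PSI-BLAST ``-out_ascii_pssm`` dialect.

    ``percentages`` is an (L, 20) integer-valued matrix in [0, 100]. The
    log-odds block is filled with zeros; only the percentage block carries
    information, matching what :func:`read_pssm` consumes.
    """
    percentages = np.asarray(percentages)
    header_aa = "  ".join(PSSM_ALPHABET)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per position, "
                 "and relative weight of gapped matches to pseudocounts\n")
        fh.write("            " + header_aa + "   " + header_aa + "\n")
        for i, (res, row) in enumerate(zip(sequence, percentages), start=1):
            scores = " ".join(f"{0:3d}" for _ in range(20))
            percs = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {res}  {scores}  {percs}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3113\n")


def read_sspre(path: str | os.PathLike) -> np.ndarray:
    """Parse a SPIDER2-style ``.spd3`` table into an (L, 3) matrix.

    File rows carry P(C), P(E), P(H) as their trailing three numeric
    columns (optionally preceded by index, residue and state columns);
    the returned matrix is reordered to the canonical (helix, strand,
    coil) columns. Rows whose probabilities sum outside [0.9, 1.1] are
    rejected.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise ProfileIOError(
                    f"{path}:{lineno}: expected at least 3 columns"
                )
            try:
                pc, pe, ph = (float(t) for t in tokens[-3:])
            except ValueError as exc:
                raise ProfileIOError(
                    f"{path}:{lineno}: non-numeric probability field"
                ) from exc
            total = pc + pe + ph
            if not (0.9 <= total <= 1.1):
                raise ProfileIOError(
                    f"{path}:{lineno}: probabilities sum to {total:.3f}, "
                    "outside [0.9, 1.1]"
                )
            # file order (C, E, H) -> canonical (H, E, C)
            rows.append([ph, pe, pc])
    if not rows:
        raise ProfileIOError(f"{path}: no residue rows found")
    return np.array(rows, dtype=float)


def write_sspre(path: str | os.PathLike, sequence: str,
                sspre: np.ndarray) -> None:
    """Emit a ``.spd3``-style table from a canonical (H, E, C) matrix."""
    sspre = np.asarray(sspre, dtype=float)
    with open(path, "w") as fh:
        fh.write("# index AA SS P(C) P(E) P(H)\n")
        for i, (res, row) in enumerate(zip(sequence, sspre), start=1):
            ph, pe, pc = row
            state = SS_STATES[int(np.argmax(row))]
            fh.write(f"{i} {res} {state} {pc:.3f} {pe:.3f} {ph:.3f}\n")


def load_profiles(fasta_path: str | os.PathLike,
                  pssm_dir: str | os.PathLike,
                  ss_dir: str | os.PathLike,
                  pssm_suffix: str = ".pssm",
                  ss_suffix: str = ".spd3") -> dict[str, ProteinProfile]:
    """Assemble :class:`ProteinProfile` objects from a FASTA plus per-protein
    profile directories (files named ``<protein_id><suffix>``).

    The PSSM residue letters must equal the FASTA sequence; a mismatch is
    an error, since silently misaligned profiles would corrupt every
    downstream feature.
    """
    pssm_dir, ss_dir = Path(pssm_dir), Path(ss_dir)
    profiles: dict[str, ProteinProfile] = {}
    for pid, seq in read_fasta(fasta_path):
        pssm_path = pssm_dir / f"{pid}{pssm_suffix}"
        ss_path = ss_dir / f"{pid}{ss_suffix}"
        if not pssm_path.exists():
            raise ProfileIOError(f"missing PSSM file for protein {pid!r}: "
                                 f"{pssm_path}")
        if not ss_path.exists():
            raise ProfileIOError(f"missing secondary-structure file for "
                                 f"protein {pid!r}: {ss_path}")
        pssm, letters = read_pssm(pssm_path)
        if letters != seq:
            raise ProfileIOError(
                f"{pid}: PSSM residue letters do not match FASTA sequence"
            )
        sspre = read_sspre(ss_path)
        if sspre.shape[0] != len(seq):
            raise ProfileIOError(
                f"{pid}: secondary-structure rows ({sspre.shape[0]}) != "
                f"sequence length ({len(seq)})"
            )
        profiles[pid] = ProteinProfile(pid, seq, pssm, sspre)
    return profiles


def read_sites(path: str | os.PathLike,
               profiles: dict[str, ProteinProfile]) -> list[SiteRecord]:
    """Parse the site-annotation TSV and validate each record.

    Columns: ``protein_id``, ``position`` (1-based), ``label`` (0/1).
    Each position must fall inside its protein and point at a lysine.
    """
    sites: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if lineno == 1 and tokens[0] == "protein_id":
                continue
            if len(tokens) != 3:
                raise ProfileIOError(f"{path}:{lineno}: expected 3 columns")
            pid, pos_s, label_s = tokens
            if pid not in profiles:
                raise ProfileIOError(
                    f"{path}:{lineno}: unknown protein {pid!r}"
                )
            try:
                pos1 = int(pos_s)
                label = int(label_s)
            except ValueError as exc:
                raise ProfileIOError(
                    f"{path}:{lineno}: non-integer position/label"
                ) from exc
            prof = profiles[pid]
            if not (1 <= pos1 <= prof.length):
                raise ProfileIOError(
                    f"{path}:{lineno}: position {pos1} outside protein "
                    f"{pid!r} (length {prof.length})"
                )
            if prof.sequence[pos1 - 1] != "K":
                raise ProfileIOError(
                    f"{path}:{lineno}: residue at {pid}:{pos1} is "
                    f"{prof.sequence[pos1 - 1]!r}, not 'K'"
                )
            sites.append(SiteRecord(pid, pos1 - 1, label))
    return sites


def write_sites(path: str | os.PathLike, sites: Sequence[SiteRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position + 1}\t{s.label}\n")
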