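"""Position-specific scoring matrices for bipartite targeting-signal cleavage sites.

Nucleus-encoded plastid and periplastidic-compartment (PPC) proteins of algae
with complex plastids carry a bipartite pre-sequence: a cleavable signal
peptide followed by a transit peptide.  The sequence surrounding the signal
peptidase cleavage site is conserved, and that conservation is what the
scoring matrices built here capture.  A matrix is trained from aligned
25-residue windows spanning positions -5..-1 (the last five signal-peptide
residues) and +1..+20 (the first twenty transit-peptide residues); there is
no position 0 -- cleavage occurs between -1 and +1.

The score of residue ``a`` at column ``i`` is sequence-logo style::

    contribution_i(a) = f_i(a) * R_i
    R_i = log2(20) - (H_i + e_n)          [e_n only when corrected]
    H_i = -sum_a f_i(a) * log2 f_i(a)
    e_n = (s - 1) / (2 * ln 2 * n),  s = 20

i.e. the observed frequency of the residue weighted by the information
content of the column, with the small-sample entropy-bias correction applied
when requested.  ``R_i`` may go negative after correction for nearly uniform
columns; it is deliberately not clamped so that score arithmetic stays
linear.  Residues never observed in a column contribute exactly 0 (no
pseudocounts): the method scores observed-frequency times information, not
log-odds.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

#: The 20 standard amino acids, fixed row order of every matrix file.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
RES_INDEX = {a: i for i, a in enumerate(RESIDUES)}

#: Window columns: -5..-1 then +1..+20 (no position 0).
POSITIONS: tuple[int, ...] = tuple(range(-5, 0)) + tuple(range(1, 21))
POSITION_LABELS: tuple[str, ...] = tuple(f"{p:+d}" if p > 0 else str(p) for p in POSITIONS)
WINDOW_LENGTH = 25
ALPHABET_SIZE = 20
MAX_INFO_BITS = math.log2(ALPHABET_SIZE)

#: Columns +1..+20, used for the transit-peptide score.
TRANSIT_SLICE = slice(5, 25)


class WindowSetError(ValueError):
    """Raised for malformed training windows (wrong length / alphabet / too few)."""


@dataclass(frozen=True)
class WindowSet:
    """Aligned 25-residue cleavage-site windows used to train a matrix."""

    windows: tuple[str, ...]
    source_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.windows)

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        source_ids: Sequence[str] | None = None,
        lenient: bool = False,
    ) -> "WindowSet":
        """Validate and assemble a window set.

        Strict mode (default) rejects any window of wrong length or with a
        non-standard residue, naming the offending record.  Lenient mode
        drops windows containing non-standard residues (X/B/Z/U/...) with a
        logged warning; wrong-length windows are always an error.
        """
        seqs = [str(s).upper() for s in sequences]
        ids = list(source_ids) if source_ids is not None else [f"w{i + 1}" for i in range(len(seqs))]
        if len(ids) != len(seqs):
            raise WindowSetError("source_ids length does not match number of windows")
        kept, kept_ids = [], []
        for i, (s, sid) in enumerate(zip(seqs, ids)):
            if len(s) != WINDOW_LENGTH:
                raise WindowSetError(
                    f"window {i} ({sid!r}) has length {len(s)}, expected {WINDOW_LENGTH}"
                )
            bad = set(s) - set(RESIDUES)
            if bad:
                if lenient:
                    log.warning("dropping window %r: non-standard residues %s", sid, sorted(bad))
                    continue
                raise WindowSetError(
                    f"window {i} ({sid!r}) contains non-standard residues {sorted(bad)}"
                )
            kept.append(s)
            kept_ids.append(sid)
        if len(kept) < 2:
            raise WindowSetError(f"need at least 2 valid windows, got {len(kept)}")
        return cls(windows=tuple(kept), source_ids=tuple(kept_ids))


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-column residue frequencies f_i(a); shape (20 residues, 25 columns)."""

    freq: np.ndarray
    n: int

    def __post_init__(self):
        sums = self.freq.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("frequency columns must each sum to 1")


@dataclass(frozen=True)
class ScoringMatrix:
    """25-column x 20-residue table of per-position contribution values.

    ``contribution[RES_INDEX[a], j] = f_j(a) * info[j]`` in bits; ``info`` is
    the (optionally small-sample corrected) information content R_j of each
    column.  ``n`` is the training-set size, ``label`` free provenance text.
    """

    contribution: np.ndarray  # (20, 25) bits
    info: np.ndarray  # (25,) bits
    n: int
    corrected: bool
    label: str = ""

    def score(self, residue: str, column: int) -> float:
        """Contribution of ``residue`` at window column index ``column`` (0..24).

        Residues outside the 20-letter standard alphabet score 0 (never
        observed in training by construction).
        """
        i = RES_INDEX.get(residue)
        return 0.0 if i is None else float(self.contribution[i, column])

    def frequencies(self) -> np.ndarray:
        """Recover f_i(a) from contribution/info where info != 0 (else 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(self.info != 0.0, self.contribution / self.info, 0.0)
        return f

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.contribution, index=list(RESIDUES), columns=list(POSITION_LABELS))


def small_sample_correction(n: int, s: int = ALPHABET_SIZE) -> float:
    """Expected entropy underestimation e_n = (s-1)/(2*ln2*n) in bits."""
    if n < 2:
        raise ValueError("insufficient sample: small-sample correction needs n >= 2")
    return (s - 1) / (2.0 * math.log(2.0) * n)


def column_frequencies(windows: WindowSet) -> FrequencyProfile:
    """Observed residue frequency per window column: count(a at i) / n."""
    counts = np.zeros((ALPHABET_SIZE, WINDOW_LENGTH), dtype=float)
    for w in windows.windows:
        for j, a in enumerate(w):
            counts[RES_INDEX[a], j] += 1.0
    return FrequencyProfile(freq=counts / windows.n, n=windows.n)


def _entropy_bits(freq_column: np.ndarray) -> float:
    f = np.asarray(freq_column, dtype=float)
    nz = f[f > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def column_information(freq_column: np.ndarray, n: int | None = None, corrected: bool = False) -> float:
    """Information content R = log2(20) - (H + e_n*[corrected]) of one column.

    ``0*log 0`` is taken as 0; R may be negative when corrected (no clamping).
    """
    f = np.asarray(freq_column, dtype=float)
    if not math.isclose(float(f.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("frequency column must sum to 1")
    h = _entropy_bits(f)
    if corrected:
        if n is None or n < 2:
            raise ValueError("insufficient sample: corrected information needs n >= 2")
        h += small_sample_correction(n)
    return MAX_INFO_BITS - h


def build_scoring_matrix(
    windows: WindowSet, corrected: bool = True, label: str = ""
) -> ScoringMatrix:
    """Train a scoring matrix: contribution[i][a] = f_i(a) * R_i."""
    prof = column_frequencies(windows)
    info = np.array(
        [column_information(prof.freq[:, j], n=prof.n, corrected=corrected) for j in range(WINDOW_LENGTH)]
    )
    contribution = prof.freq * info[np.newaxis, :]
    return ScoringMatrix(contribution=contribution, info=info, n=prof.n, corrected=corrected, label=label)


# ---------------------------------------------------------------------------
# Matrix file dialect: TSV with '# key=value' metadata comments, a header row
# of the 25 position labels, 20 data rows in fixed residue order, and an
# optional trailing 'info' row.  Values at 6 decimal places.
# ---------------------------------------------------------------------------

class MatrixParseError(ValueError):
    pass


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# label={matrix.label}",
        f"# n={matrix.n}",
        f"# corrected={matrix.corrected}",
        "\t".join(["residue", *POSITION_LABELS]),
    ]
    for i, a in enumerate(RESIDUES):
        lines.append("\t".join([a, *(f"{v:.6f}" for v in matrix.contribution[i])]))
    lines.append("\t".join(["info", *(f"{v:.6f}" for v in matrix.info)]))
    path.write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> ScoringMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}
    info: list[float] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*=\s*(.*)$", line)
            if m:
                meta[m.group(1)] = m.group(2).strip()
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            if parts[0] != "residue" or tuple(parts[1:]) != POSITION_LABELS:
                raise MatrixParseError(
                    f"line {lineno}: expected header 'residue' plus the {WINDOW_LENGTH} "
                    f"position labels {'/'.join(POSITION_LABELS[:3])}.../{POSITION_LABELS[-1]}"
                )
            continue
        key, *cells = parts
        if len(cells) != WINDOW_LENGTH:
            raise MatrixParseError(
                f"line {lineno}: expected {WINDOW_LENGTH} value columns, got {len(cells)}"
            )
        try:
            values = [float(c) for c in cells]
        except ValueError as exc:
            raise MatrixParseError(f"line {lineno}: non-numeric cell ({exc})") from None
        if key == "info":
            info = values
        else:
            rows[key] = values
    if header is None:
        raise MatrixParseError("empty matrix file")
    missing = [a for a in RESIDUES if a not in rows]
    if missing:
        raise MatrixParseError(f"missing residue rows: {missing}")
    contribution = np.array([rows[a] for a in RESIDUES])
    if info is None:
        # tolerate files without the optional info row: recover as column sum
        # of contributions (exact identity when every residue row is present).
        info_arr = contribution.sum(axis=0)
    else:
        info_arr = np.array(info)
    return ScoringMatrix(
        contribution=contribution,
        info=info_arr,
        n=int(meta.get("n", 0)),
        corrected=meta.get("corrected", "False").lower() in {"true", "1", "yes"},
        label=meta.get("label", ""),
    )


def logo_heights(matrix: ScoringMatrix) -> list[list[tuple[str, float]]]:
    """Per-column stacked residue heights: (residue, contribution), tallest first.

    Only residues observed in training appear (frequency > 0); the column
    total equals info[i] times the summed frequency of residues present,
    i.e. exactly info[i] for a complete frequency column.
    """
    freq = matrix.frequencies()
    out: list[list[tuple[str, float]]] = []
    for j in range(WINDOW_LENGTH):
        col = [
            (RESIDUES[i], float(matrix.contribution[i, j]))
            for i in range(ALPHABET_SIZE)
            if (freq[i, j] > 0.0 or matrix.contribution[i, j] != 0.0)
        ]
        col.sort(key=lambda t: (-t[1], t[0]))
        out.append(col)
    return out


class CleavageSiteMatrix(BaseEstimator, TransformerMixin):
    """Estimator wrapper: fit a cleavage-site scoring matrix from 25-mers.

    Parameters
    ----------
    corrected : bool, default True
        Apply the small-sample information correction e_n.
    label : str
        Free provenance text stored with the matrix.
    lenient : bool, default False
        Drop (rather than reject) training windows with non-standard residues.

    Attributes
    ----------
    matrix_ : ScoringMatrix
    freq_ : ndarray of shape (20, 25)
    info_ : ndarray of shape (25,)
    contribution_ : ndarray of shape (20, 25)
    n_ : int
    """

    def __init__(self, corrected: bool = True, label: str = "", lenient: bool = False):
        self.corrected = corrected
        self.label = label
        self.lenient = lenient

    def fit(self, X, y=None):
        ws = X if isinstance(X, WindowSet) else WindowSet.from_sequences(X, lenient=self.lenient)
        self.matrix_ = build_scoring_matrix(ws, corrected=self.corrected, label=self.label)
        self.freq_ = self.matrix_.frequencies()
        self.info_ = self.matrix_.info
        self.contribution_ = self.matrix_.contribution
        self.n_ = self.matrix_.n
        return self

    def transform(self, X):
        """Score 25-mers against the fitted matrix: sum of per-column contributions."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "matrix_")
        scores = []
        for w in X:
            w = str(w).upper()
            if len(w) != WINDOW_LENGTH:
                raise ValueError(f"expected {WINDOW_LENGTH}-mers, got length {len(w)}")
            scores.append(sum(self.matrix_.score(a, j) for j, a in enumerate(w)))
        return np.asarray(scores, dtype=float).reshape(-1, 1)
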