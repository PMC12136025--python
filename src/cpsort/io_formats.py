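"""Input/output: protein FASTA and the short-format dialects of upstream
signal-peptide predictors (TargetP 2.0, SignalP 5.0, SignalP 4.x, SignalP 3.0
NN), unified into :class:`SignalPrediction` records, plus the results table.

Coordinate convention: ``cleavage_site`` is the 1-based position of the LAST
signal-peptide residue; the transit peptide's "+1" residue is at
``cleavage_site + 1``.  This matches the ``CS pos: a-b`` reporting of
TargetP 2 / SignalP 5, where cleavage occurs between residues a and b.
For SignalP 4 / SignalP 3 NN, whose Ymax position is the first mature
residue, the site is Ymax position minus 1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

DIALECTS = ("targetp2", "signalp5", "signalp4", "signalp3nn")

#: upstream predictor categories fed into the decision tree
CATEGORIES = ("SP", "mTP", "other")


class PredictorParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein record with empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has empty sequence")


@dataclass(frozen=True)
class SignalPrediction:
    """One upstream predictor's verdict for one protein.

    ``category`` is SP / mTP / other (the SignalP tools only produce SP /
    other; mTP exists only for TargetP 2).  ``cleavage_site`` is present for
    usable SP calls; an SP call whose cleavage site could not be parsed is
    kept with ``site_known=False`` and is treated downstream as
    "SP, site-unknown" (never plastid/PPC).
    """

    id: str
    tool: str
    category: str
    cleavage_site: int | None = None
    score: float | None = None
    site_known: bool = True

    def __post_init__(self):
        if self.tool not in DIALECTS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "SP" and self.site_known:
            if self.cleavage_site is None or self.cleavage_site < 1:
                raise ValueError(f"SP prediction for {self.id!r} needs cleavage_site >= 1")


def read_fasta(path: str | Path, dedup_policy: str = "error") -> list[ProteinRecord]:
    """Read a protein FASTA; ids are the first whitespace token of the header.

    ``dedup_policy``: "error" rejects duplicate ids; "first" keeps the first
    occurrence with a logged warning.
    """
    if dedup_policy not in {"error", "first"}:
        raise ValueError(f"unknown dedup_policy {dedup_policy!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            if dedup_policy == "error":
                raise ValueError(f"duplicate FASTA id {rid!r}")
            log.warning("duplicate FASTA id %r: keeping first occurrence", rid)
            continue
        seen.add(rid)
        records.append(ProteinRecord(id=rid, description=rec.description, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


_CS_RE = re.compile(r"CS pos:\s*(\d+)-(\d+)")
_PR_RE = re.compile(r"Pr:\s*([0-9.]+)")


def _parse_cs(text: str) -> tuple[int | None, float | None]:
    m = _CS_RE.search(text)
    if not m:
        return None, None
    a, b = int(m.group(1)), int(m.group(2))
    if b != a + 1:
        raise PredictorParseError(f"inconsistent CS pos {a}-{b} (expected b = a+1)")
    pm = _PR_RE.search(text)
    return a, (float(pm.group(1)) if pm else None)


def _data_lines(path: Path) -> list[tuple[int, str]]:
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.strip() and not raw.lstrip().startswith("#"):
            out.append((lineno, raw.rstrip()))
    return out


def _header_text(path: Path) -> str:
    return "\n".join(l for l in path.read_text().splitlines() if l.lstrip().startswith("#"))


def _check_header(path: Path, dialect: str) -> None:
    """Reject a file whose comment header names a different known tool."""
    head = _header_text(path)
    marks = {
        "targetp2": "TargetP-2",
        "signalp5": "SignalP-5",
        "signalp4": "SignalP-4",
        "signalp3nn": "SignalP-3.0",
    }
    for d, mark in marks.items():
        if d != dialect and mark in head:
            raise PredictorParseError(
                f"file header names {mark} but dialect {dialect!r} was claimed"
            )
    if "cTP" in head or "Organism: Plant" in head:
        raise PredictorParseError(
            "plant-mode TargetP output detected; run the upstream predictor "
            "with the non-plant organism group"
        )


def _parse_targetp2(path: Path) -> list[SignalPrediction]:
    # columns: ID  Prediction  noTP  SP  mTP  [CS Position]
    preds = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 5:
            parts = line.split()
        if len(parts) < 5:
            raise PredictorParseError(f"line {lineno}: expected >=5 TargetP 2 columns")
        rid, verdict = parts[0], parts[1]
        rest = "\t".join(parts[5:])
        if verdict == "SP":
            site, pr = _parse_cs(rest)
            if site is None:
                preds.append(SignalPrediction(rid, "targetp2", "SP", None, float(parts[3]), site_known=False))
            else:
                preds.append(SignalPrediction(rid, "targetp2", "SP", site, pr if pr is not None else float(parts[3])))
        elif verdict == "mTP":
            preds.append(SignalPrediction(rid, "targetp2", "mTP", None, float(parts[4])))
        elif verdict in {"noTP", "OTHER", "Other"}:
            preds.append(SignalPrediction(rid, "targetp2", "other", None, float(parts[2])))
        elif verdict == "cTP":
            raise PredictorParseError(
                f"line {lineno}: plant-mode cTP prediction; non-plant output required"
            )
        else:
            raise PredictorParseError(f"line {lineno}: unknown TargetP 2 verdict {verdict!r}")
    return preds


def _parse_signalp5(path: Path) -> list[SignalPrediction]:
    # columns: ID  Prediction  SP(Sec/SPI)  OTHER  [CS Position]
    preds = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            parts = line.split()
        if len(parts) < 4:
            raise PredictorParseError(f"line {lineno}: expected >=4 SignalP 5 columns")
        rid, verdict = parts[0], parts[1]
        rest = "\t".join(parts[4:])
        if verdict.startswith("SP"):
            site, pr = _parse_cs(rest)
            if site is None:
                preds.append(SignalPrediction(rid, "signalp5", "SP", None, float(parts[2]), site_known=False))
            else:
                preds.append(SignalPrediction(rid, "signalp5", "SP", site, pr if pr is not None else float(parts[2])))
        elif verdict.upper() == "OTHER":
            preds.append(SignalPrediction(rid, "signalp5", "other", None, float(parts[3])))
        else:
            raise PredictorParseError(f"line {lineno}: unknown SignalP 5 verdict {verdict!r}")
    return preds


def _parse_signalp4(path: Path) -> list[SignalPrediction]:
    # columns: name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut Networks-used
    preds = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 12:
            raise PredictorParseError(f"line {lineno}: expected 12 SignalP 4 columns, got {len(parts)}")
        rid = parts[0]
        try:
            ymax_pos = int(parts[4])
            d_score = float(parts[8])
        except ValueError as exc:
            raise PredictorParseError(f"line {lineno}: bad numeric field ({exc})") from None
        decision = parts[9]
        if decision not in {"Y", "N"}:
            raise PredictorParseError(f"line {lineno}: SignalP 4 decision must be Y/N, got {decision!r}")
        if decision == "Y":
            site = ymax_pos - 1
            if site < 1:
                preds.append(SignalPrediction(rid, "signalp4", "SP", None, d_score, site_known=False))
            else:
                preds.append(SignalPrediction(rid, "signalp4", "SP", site, d_score))
        else:
            preds.append(SignalPrediction(rid, "signalp4", "other", None, d_score))
    return preds


def _parse_signalp3nn(path: Path) -> list[SignalPrediction]:
    # standalone NN summary: name Cmax pos ? Ymax pos ? Smax pos ? Smean ? D ?
    preds = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 14:
            raise PredictorParseError(
                f"line {lineno}: expected 14 SignalP 3 NN summary columns, got {len(parts)}"
            )
        rid = parts[0]
        try:
            ymax_pos = int(parts[5])
            d_score = float(parts[12])
        except ValueError as exc:
            raise PredictorParseError(f"line {lineno}: bad numeric field ({exc})") from None
        decision = parts[13]
        if decision not in {"Y", "N"}:
            raise PredictorParseError(f"line {lineno}: SignalP 3 decision must be Y/N, got {decision!r}")
        if decision == "Y":
            site = ymax_pos - 1
            if site < 1:
                preds.append(SignalPrediction(rid, "signalp3nn", "SP", None, d_score, site_known=False))
            else:
                preds.append(SignalPrediction(rid, "signalp3nn", "SP", site, d_score))
        else:
            preds.append(SignalPrediction(rid, "signalp3nn", "other", None, d_score))
    return preds


_PARSERS = {
    "targetp2": _parse_targetp2,
    "signalp5": _parse_signalp5,
    "signalp4": _parse_signalp4,
    "signalp3nn": _parse_signalp3nn,
}


def parse_predictor_output(path: str | Path, dialect: str = "targetp2") -> list[SignalPrediction]:
    """Parse an upstream predictor's short-format output into unified records."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    _check_header(path, dialect)
    preds = _PARSERS[dialect](path)
    if not preds:
        raise PredictorParseError(f"no prediction rows found in {path}")
    return preds


def match_predictions(
    proteins: Sequence[ProteinRecord],
    predictions: Sequence[SignalPrediction],
    strict: bool = True,
) -> dict[str, SignalPrediction]:
    """Join predictions to proteins by id.

    Exact first-token match first; failing that, a unique-prefix match
    (upstream tools truncate long ids).  Under ``strict``, a protein without
    any matching prediction is an error; otherwise it is skipped with a
    warning by the caller.
    """
    by_id = {p.id: p for p in predictions}
    out: dict[str, SignalPrediction] = {}
    for prot in proteins:
        if prot.id in by_id:
            out[prot.id] = by_id[prot.id]
            continue
        prefixes = [p for pid, p in by_id.items() if prot.id.startswith(pid)]
        if len(prefixes) == 1:
            out[prot.id] = prefixes[0]
        elif strict:
            raise KeyError(f"no prediction record matches protein id {prot.id!r}")
    return out


RESULT_COLUMNS = (
    "id",
    "input_category",
    "cleavage_site",
    "window_score",
    "transit_score_plastid",
    "transit_score_ppc",
    "plus1_residue",
    "category",
    "confidence",
    "flags",
)


def write_predictions_table(results: Iterable, path: str | Path) -> None:
    """Write targeting results as TSV, one row per protein in input order."""
    path = Path(path)
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.input_category,
                    "NA" if r.scan is None else str(r.scan.best_site),
                    "NA" if r.scan is None else f"{r.scan.best_window_score:.6f}",
                    "NA" if r.transit_score_plastid is None else f"{r.transit_score_plastid:.6f}",
                    "NA" if r.transit_score_ppc is None else f"{r.transit_score_ppc:.6f}",
                    r.plus1_residue or "NA",
                    r.category,
                    r.confidence,
                    ";".join(r.flags) if r.flags else "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
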