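"""Synthetic data generation and brute-force oracles.

Everything here exists so the whole pipeline is testable without running the
external signal-peptide predictors or downloading proteomes: training-window
sampling from parameterised cleavage-site profiles, synthetic proteomes with
planted bipartite targeting signals plus matching emulated predictor output
files, and a deliberately naive re-scoring oracle kept separate from the
predictor code.

The default profiles emulate the contrast between plastid and periplastidic
compartment (PPC) pre-sequences: both share the signal-peptidase cleavage
motif (small residues at -3/-1), but plastid transit peptides start with a
conserved phenylalanine (or Y/W/L) and draw from an uncharged residue pool
-- real plastid transit peptides are nearly devoid of negative charges near
the cleavage site -- while PPC transit peptides lack the +1 aromatic and
carry both negative and positive charges throughout.  The generator
exaggerates this pool separation (disjoint residue pools downstream of the
cleavage site) so that planted classes are recoverable by construction; see
the methods note for what that does and does not demonstrate about real
proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ProteinRecord
from .matrixlib import RESIDUES, WINDOW_LENGTH, ScoringMatrix, WindowSet

#: residue pools realising the charge contrast between compartments
UNCHARGED_POOL = "ASTVLIMFYWP"
CHARGED_POOL = "DEKRNQGH"
HYDROPHOBIC_CORE = "LVAFI"

PLAN_CLASSES = ("plastid", "PPC", "SP-other", "mTP", "other")

#: reference-set-like class mix (plastid : PPC : secretory : mito : other)
REFERENCE_MIX = {"plastid": 71, "PPC": 44, "SP-other": 92, "mTP": 26, "other": 29}


@dataclass(frozen=True)
class ProfileSpec:
    """Stochastic 25-column cleavage-site profile.

    Per column: with probability ``conservation[j]`` the consensus residue is
    drawn, otherwise a uniform draw from ``allowed[j]`` minus the consensus
    (the decoy set).  Restricting ``allowed`` encodes charge constraints.
    """

    consensus: str
    conservation: tuple[float, ...]
    allowed: tuple[str, ...]

    def __post_init__(self):
        if len(self.consensus) != WINDOW_LENGTH:
            raise ValueError("consensus must have 25 residues")
        if len(self.conservation) != WINDOW_LENGTH or len(self.allowed) != WINDOW_LENGTH:
            raise ValueError("conservation and allowed must have 25 entries")
        if any(not 0.0 <= c <= 1.0 for c in self.conservation):
            raise ValueError("conservation values must be in [0, 1]")
        for j, pool in enumerate(self.allowed):
            if set(pool) - set(RESIDUES):
                raise ValueError(f"allowed pool at column {j} has non-standard residues")

    def decoys(self, j: int) -> str:
        return "".join(a for a in self.allowed[j] if a != self.consensus[j])

    def with_conservation(self, c: float) -> "ProfileSpec":
        """Uniform-conservation variant (profile sweep in tests)."""
        return ProfileSpec(self.consensus, tuple([c] * WINDOW_LENGTH), self.allowed)


#: conservation shape: strong -3/-1 signal-peptidase constraint, very strong
#: +1, moderate elsewhere
_SP_CONS = (0.60, 0.50, 0.90, 0.50, 0.90)
_PLASTID_CONSENSUS = "ASASA" + "F" + "APSSTASSVASTLSAASTS"
_PPC_CONSENSUS = "ASASA" + "G" + "NDKEQGNDKHEQGKDNEQK"
_SECRETORY_CONSENSUS = "ASASA" + "D" + "EKGNQHDEKGNQHDEKGNQ"


def default_plastid_profile() -> ProfileSpec:
    conservation = _SP_CONS + (0.95,) + (0.45,) * 19
    allowed = (UNCHARGED_POOL,) * 5 + ("FYWL",) + (UNCHARGED_POOL,) * 19
    return ProfileSpec(_PLASTID_CONSENSUS, conservation, allowed)


def default_ppc_profile() -> ProfileSpec:
    conservation = _SP_CONS + (0.90,) + (0.45,) * 19
    allowed = (UNCHARGED_POOL,) * 5 + (CHARGED_POOL,) * 20
    return ProfileSpec(_PPC_CONSENSUS, conservation, allowed)


def default_secretory_profile() -> ProfileSpec:
    """Generic secretory signal: conserved cleavage motif, unstructured rest."""
    conservation = _SP_CONS + (0.0,) * 20
    allowed = (UNCHARGED_POOL,) * 5 + (CHARGED_POOL,) * 20
    return ProfileSpec(_SECRETORY_CONSENSUS, conservation, allowed)


def sample_window(profile: ProfileSpec, rng: np.random.Generator) -> str:
    out = []
    for j in range(WINDOW_LENGTH):
        if rng.random() < profile.conservation[j]:
            out.append(profile.consensus[j])
        else:
            decoys = profile.decoys(j)
            out.append(decoys[rng.integers(len(decoys))])
    return "".join(out)


def sample_windows(profile: ProfileSpec, n: int, seed: int) -> WindowSet:
    """Draw ``n`` i.i.d. training windows; deterministic given ``seed``."""
    if n < 2:
        raise ValueError("need n >= 2 windows")
    rng = np.random.default_rng(seed)
    windows = [sample_window(profile, rng) for _ in range(n)]
    ids = [f"synthetic_{i + 1:03d}" for i in range(n)]
    return WindowSet(windows=tuple(windows), source_ids=tuple(ids))


@dataclass(frozen=True)
class PlantPlan:
    """Per-class protein counts and the seed that makes a proteome reproducible."""

    counts: Mapping[str, int]
    seed: int
    conservation: float | None = None  # None: profiles' built-in shapes
    site_range: tuple[int, int] = (16, 25)
    mature_range: tuple[int, int] = (25, 60)

    def __post_init__(self):
        stray = set(self.counts) - set(PLAN_CLASSES)
        if stray:
            raise ValueError(f"unknown plan classes: {sorted(stray)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative class count")

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class TruthRecord:
    id: str
    truth: str
    site: int | None


@dataclass(frozen=True)
class SyntheticProteome:
    proteins: tuple[ProteinRecord, ...]
    truth: tuple[TruthRecord, ...]
    predictor_text: str
    dialect: str
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "proteins.fasta"
        with fasta.open("w") as fh:
            for p in self.proteins:
                fh.write(f">{p.id} {p.description}\n{p.sequence}\n")
        pred = outdir / f"{self.dialect}.short"
        pred.write_text(self.predictor_text)
        truth = outdir / "truth.tsv"
        lines = [f"# seed={self.seed}", "id\ttruth\tsite"]
        for t in self.truth:
            lines.append(f"{t.id}\t{t.truth}\t{'NA' if t.site is None else t.site}")
        truth.write_text("\n".join(lines) + "\n")
        return {"fasta": fasta, "predictor": pred, "truth": truth}


def _draw(pool: str, n: int, rng: np.random.Generator) -> str:
    return "".join(pool[i] for i in rng.integers(len(pool), size=n))


_PREDICTOR_HEADERS = {
    "targetp2": "# TargetP-2.0\tOrganism: Non-Plant\n# ID\tPrediction\tnoTP\tSP\tmTP\tCS Position\n",
    "signalp5": "# SignalP-5.0\tOrganism: Eukarya\n# ID\tPrediction\tSP(Sec/SPI)\tOTHER\tCS Position\n",
    "signalp4": (
        "# SignalP-4.1 euk predictions\n"
        "# name                     Cmax  pos  Ymax  pos  Smax  pos  Smean   D     ?  Dmaxcut    Networks-used\n"
    ),
    "signalp3nn": (
        "# SignalP-3.0 NN euk predictions\n"
        "# name  Cmax  pos  ?  Ymax  pos  ?  Smax  pos  ?  Smean  ?  D  ?\n"
    ),
}


def expected_upstream_category(truth_class: str, dialect: str) -> str:
    """Category the emulated upstream predictor reports for a planted class."""
    if truth_class in {"plastid", "PPC", "SP-other"}:
        return "SP"
    if truth_class == "mTP":
        return "mTP" if dialect == "targetp2" else "other"
    return "other"


def _predictor_line(dialect: str, rid: str, truth_class: str, site: int | None,
                    rng: np.random.Generator) -> str:
    cat = expected_upstream_category(truth_class, dialect)
    pr = round(float(rng.uniform(0.90, 0.99)), 4)
    lo = round(float(rng.uniform(0.005, 0.04)), 4)
    if dialect == "targetp2":
        if cat == "SP":
            return f"{rid}\tSP\t{lo:.6f}\t{pr:.6f}\t{lo:.6f}\tCS pos: {site}-{site + 1}. Pr: {pr:.4f}"
        if cat == "mTP":
            return f"{rid}\tmTP\t{lo:.6f}\t{lo:.6f}\t{pr:.6f}\t"
        return f"{rid}\tnoTP\t{pr:.6f}\t{lo:.6f}\t{lo:.6f}\t"
    if dialect == "signalp5":
        if cat == "SP":
            return f"{rid}\tSP(Sec/SPI)\t{pr:.6f}\t{lo:.6f}\tCS pos: {site}-{site + 1}. Pr: {pr:.4f}"
        return f"{rid}\tOTHER\t{lo:.6f}\t{pr:.6f}\t"
    if dialect == "signalp4":
        ymax = (site + 1) if cat == "SP" else 10
        d = pr if cat == "SP" else lo
        flag = "Y" if cat == "SP" else "N"
        return (
            f"{rid:<26s} {pr:.3f} {ymax:3d}  {pr:.3f} {ymax:3d}  {pr:.3f}   7  {pr:.3f}  "
            f"{d:.3f} {flag}  0.450      SignalP-noTM"
        )
    if dialect == "signalp3nn":
        ymax = (site + 1) if cat == "SP" else 10
        d = pr if cat == "SP" else lo
        flag = "Y" if cat == "SP" else "N"
        return (
            f"{rid}  {pr:.3f}  {ymax} {flag}  {pr:.3f}  {ymax} {flag}  {pr:.3f}  7 {flag}  "
            f"{pr:.3f} {flag}  {d:.3f} {flag}"
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def synth_proteome(plan: PlantPlan, dialect: str = "targetp2") -> SyntheticProteome:
    """Generate a proteome with planted targeting signals plus the matching
    emulated upstream-predictor file and a truth table.

    Plastid-class proteins carry a window from the plastid profile at the
    planted cleavage site (+1 in F/Y/W/L by construction); PPC-class proteins
    a PPC-profile window (+1 never F/Y/W/L); secretory proteins the cleavage
    motif followed by an unstructured charged region; mitochondrial and
    untargeted proteins are unstructured and carry no cleavage site.
    """
    rng = np.random.default_rng(plan.seed)
    profiles = {
        "plastid": default_plastid_profile(),
        "PPC": default_ppc_profile(),
        "SP-other": default_secretory_profile(),
    }
    if plan.conservation is not None:
        profiles = {
            k: (p.with_conservation(plan.conservation) if k != "SP-other" else p)
            for k, p in profiles.items()
        }
    tail_pool = {"plastid": UNCHARGED_POOL, "PPC": CHARGED_POOL, "SP-other": CHARGED_POOL}

    proteins: list[ProteinRecord] = []
    truth: list[TruthRecord] = []
    pred_lines: list[str] = []
    counter = 0
    for cls in PLAN_CLASSES:
        for _ in range(int(plan.counts.get(cls, 0))):
            counter += 1
            rid = f"syn{counter:04d}_{cls.replace('-', '')}"
            if cls in profiles:
                site = int(rng.integers(plan.site_range[0], plan.site_range[1] + 1))
                pre = "M" + _draw(HYDROPHOBIC_CORE, site - 6, rng)  # positions 1..site-5
                window = sample_window(profiles[cls], rng)  # site-4..site+20
                tail = _draw(tail_pool[cls], int(rng.integers(*plan.mature_range)), rng)
                seq = pre + window + tail
                truth.append(TruthRecord(rid, cls, site))
                pred_lines.append(_predictor_line(dialect, rid, cls, site, rng))
            else:
                seq = "M" + _draw(RESIDUES, int(rng.integers(80, 140)), rng)
                truth.append(TruthRecord(rid, cls, None))
                pred_lines.append(_predictor_line(dialect, rid, cls, None, rng))
            proteins.append(
                ProteinRecord(id=rid, description=f"synthetic {cls} seed={plan.seed}", sequence=seq)
            )
    text = _PREDICTOR_HEADERS[dialect] + "\n".join(pred_lines) + "\n"
    return SyntheticProteome(
        proteins=tuple(proteins),
        truth=tuple(truth),
        predictor_text=text,
        dialect=dialect,
        seed=plan.seed,
    )


def oracle_score(sequence: str, site: int, matrix: ScoringMatrix, span: str = "window25") -> float:
    """Naive position-by-position re-scoring, independent of the predictor.

    ``span``: "window25" sums all 25 columns, "transit20" only +1..+20.
    Residues outside the sequence (or outside the standard alphabet)
    contribute nothing.
    """
    if span not in {"window25", "transit20"}:
        raise ValueError(f"unknown span {span!r}")
    offsets = (list(range(-5, 0)) + list(range(1, 21))) if span == "window25" else list(range(1, 21))
    col0 = 0 if span == "window25" else 5
    total = 0.0
    for k, off in enumerate(offsets):
        pos = site + off + (1 if off < 0 else 0)  # no position 0 in the window
        if pos < 1 or pos > len(sequence):
            continue
        residue = sequence[pos - 1]
        row = RESIDUES.find(residue)
        if row >= 0:
            total += float(matrix.contribution[row, col0 + k])
    return total


def calibrate_ppc_threshold(
    seed: int = 2001,
    grid: Sequence[float] | None = None,
    target_precision: float = 0.75,
) -> float:
    """Choose the PPC transit-score cut-off on the packaged synthetic benchmark.

    Generates a reference-mix proteome, classifies it with the packaged
    default matrices across a threshold grid, and returns the smallest grid
    value whose PPC precision reaches ``target_precision``.  The shipped
    default threshold was produced by this function at its default arguments
    and then frozen.
    """
    from .data import default_plastid_matrix, default_ppc_matrix
    from .predictor import PredictorConfig, predict_batch
    from .io_formats import parse_predictor_output

    if grid is None:
        grid = [round(0.25 * i, 2) for i in range(0, 81)]
    proteome = synth_proteome(PlantPlan(counts=REFERENCE_MIX, seed=seed))
    import io, tempfile

    with tempfile.TemporaryDirectory() as tmp:
        paths = proteome.write(tmp)
        preds = parse_predictor_output(paths["predictor"], "targetp2")
    truth_by_id = {t.id: t.truth for t in proteome.truth}
    base = PredictorConfig(
        plastid_matrix=default_plastid_matrix(), ppc_matrix=default_ppc_matrix(), t_ppc=0.0
    )
    results = predict_batch(list(proteome.proteins), preds, base)
    # at t_ppc = 0 every SP, non-plastid protein with a non-aromatic +1 is a
    # PPC call; raising the threshold only removes calls with lower scores
    candidates = [
        (r.transit_score_ppc, truth_by_id[r.id] == "PPC")
        for r in results
        if r.category == "PPC"
    ]
    for t in grid:
        calls = [is_ppc for score, is_ppc in candidates if score >= t]
        if calls and sum(calls) / len(calls) >= target_precision:
            return float(t)
    raise RuntimeError("no grid threshold reaches the target precision")
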