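"""Synthetic target/decoy datasets with known ground truth.

The PSM generator emulates a search against a concatenated target/decoy
database with competition: each spectrum yields one engine-A PSM, which is
a correct target match with the group-specific true fraction, and
otherwise a wrong match landing on the decoy or the target section with
odds set by ``decoy_ratio`` (1.0 reproduces the usual half/half split, so
decoy counts estimate wrong target counts).  Scores are drawn from two
3-variate normal distributions — correct matches score higher on XCorr
with positive XCorr/deltaCn correlation, wrong matches score low and
nearly independently — and decoys are drawn from the wrong-match
distribution (target/decoy symmetry).  Engine B is emitted as an already
thresholded table: it reproduces a correct engine-A match with probability
``engineB_agreement``, reproduces the *same* wrong match with probability
``engineB_false_overlap``, and otherwise either reports a different wrong
match or nothing.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from newance.io_formats import (
    Engine,
    ExpressionTable,
    FastaEntry,
    Group,
    PsmRecord,
    PsmTable,
)
from newance.qc_validation import PeptideAnnotation

__all__ = [
    "ScoreModel",
    "SimulationConfig",
    "LabeledPsmSet",
    "simulate_psms",
    "simulate_transcriptome",
    "simulate_proteome_with_peptides",
    "simulate_annotations",
    "config_for_total",
]

_AA = np.frombuffer(b"ACDEFGHKLMNPQRSTVWY", dtype="S1")  # no I: I/L-collapse safe
_NT = np.frombuffer(b"ACGT", dtype="S1")


def _random_peptides(rng: np.random.Generator, n: int, length: int = 9) -> np.ndarray:
    """Vectorised random peptide strings."""
    idx = rng.integers(0, len(_AA), size=(n, length))
    return _AA[idx].view(f"S{length}").ravel().astype(str)


@dataclass(slots=True)
class ScoreModel:
    """Two 3-variate normal components over (XCorr, deltaCn, spScore)."""

    mean_true: tuple[float, float, float] = (2.6, 0.18, 280.0)
    mean_false: tuple[float, float, float] = (1.5, 0.06, 110.0)
    cov_true: tuple[tuple[float, ...], ...] = (
        (0.64, 0.048, 48.0),
        (0.048, 0.0144, 3.6),
        (48.0, 3.6, 22500.0),
    )
    cov_false: tuple[tuple[float, ...], ...] = (
        (0.25, 0.0025, 3.0),
        (0.0025, 0.0025, 0.3),
        (3.0, 0.3, 3600.0),
    )

    def draw(self, rng: np.random.Generator, n: int, true: bool) -> np.ndarray:
        mean = self.mean_true if true else self.mean_false
        cov = self.cov_true if true else self.cov_false
        x = rng.multivariate_normal(mean, np.asarray(cov), size=n, method="cholesky")
        x[:, 1] = np.clip(x[:, 1], 0.0, 1.0)  # deltaCn is a ratio in [0, 1]
        x[:, 2] = np.maximum(x[:, 2], 0.0)  # spScore is non-negative
        return x


@dataclass(slots=True)
class SimulationConfig:
    seed: int = 0
    n_psms_per_stratum: dict = field(
        default_factory=lambda: {"Z1": 20_000, "Z2": 120_000, "Z3plus": 60_000}
    )
    fraction_noncanonical: float = 0.1
    true_fraction_proteome: float = 0.9
    true_fraction_noncanonical: float = 0.3
    decoy_ratio: float = 1.0  # expected decoys per wrong target match
    decoy_symmetry: bool = True
    score_model: ScoreModel = field(default_factory=ScoreModel)
    engineB_agreement: float = 0.9
    engineB_false_overlap: float = 0.1
    engineB_false_other: float = 0.4
    peptide_length: int = 9

    def validate(self) -> None:
        for name in (
            "fraction_noncanonical",
            "true_fraction_proteome",
            "true_fraction_noncanonical",
            "engineB_agreement",
            "engineB_false_overlap",
            "engineB_false_other",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.engineB_false_overlap + self.engineB_false_other > 1:
            raise ValueError("engineB false probabilities exceed 1")
        if self.decoy_ratio < 0:
            raise ValueError("decoy_ratio must be >= 0")


@dataclass(slots=True)
class LabeledPsmSet:
    psms_engineA: PsmTable
    psms_engineB: PsmTable
    truth: dict  # (spectrum_key, engine value) -> is_correct

    def realized_fdp(self, accepted: list[PsmRecord], engine: Engine = Engine.engineA) -> float:
        """Fraction of wrong matches among an accepted PSM list."""
        if not accepted:
            return float("nan")
        wrong = sum(
            not self.truth[(r.spectrum_key, Engine(engine).value)] for r in accepted
        )
        return wrong / len(accepted)


def _charge_for(rng: np.random.Generator, stratum: str, n: int) -> np.ndarray:
    if stratum == "Z1":
        return np.ones(n, dtype=int)
    if stratum == "Z2":
        return np.full(n, 2, dtype=int)
    return rng.choice([3, 4], size=n, p=[0.8, 0.2])


def simulate_psms(config: SimulationConfig) -> LabeledPsmSet:
    """Generate matched engine-A / engine-B PSM tables with truth labels.

    Engine A carries the full (XCorr, deltaCn, spScore) triple plus decoys;
    engine B is decoy-free and pre-thresholded, with a single score that is
    a noisy monotone transform of match quality.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rowsA: list[PsmRecord] = []
    rowsB: list[PsmRecord] = []
    truth: dict = {}

    p_decoy_given_false = config.decoy_ratio / (1.0 + config.decoy_ratio)
    for stratum, n in sorted(config.n_psms_per_stratum.items()):
        if n <= 0:
            continue
        noncanon = rng.random(n) < config.fraction_noncanonical
        true_frac = np.where(
            noncanon, config.true_fraction_noncanonical, config.true_fraction_proteome
        )
        is_true = rng.random(n) < true_frac
        is_decoy = ~is_true & (rng.random(n) < p_decoy_given_false)

        scores = np.empty((n, 3))
        scores[is_true] = config.score_model.draw(rng, int(is_true.sum()), True)
        n_false = int((~is_true).sum())
        # decoys and wrong targets share the wrong-match score distribution
        scores[~is_true] = config.score_model.draw(rng, n_false, False)

        charges = _charge_for(rng, stratum, n)
        peptides = _random_peptides(rng, n, config.peptide_length)
        engineB_score = 10.0 * scores[:, 0] + rng.normal(0, 1.0, n)

        uB_true = rng.random(n)
        uB_false = rng.random(n)
        alt_peptides = _random_peptides(rng, n, config.peptide_length)

        for i in range(n):
            key = f"{stratum}:{i:07d}"
            group = Group.noncanonical if noncanon[i] else Group.proteome
            decoy = bool(is_decoy[i])
            if decoy:
                acc = ("DECOY_nc|%06d" if noncanon[i] else "DECOY_sp|%06d") % i
            else:
                acc = ("nc|%06d" if noncanon[i] else "sp|%06d") % i
            rowsA.append(
                PsmRecord(
                    spectrum_key=key,
                    peptide=peptides[i],
                    charge=int(charges[i]),
                    xcorr=float(scores[i, 0]),
                    delta_cn=float(scores[i, 1]),
                    sp_score=float(scores[i, 2]),
                    engine_score=float(engineB_score[i]),
                    protein_ids=(acc,),
                    is_decoy=decoy,
                    group=group,
                )
            )
            truth[(key, Engine.engineA.value)] = bool(is_true[i])
            if decoy:
                continue
            if is_true[i]:
                if uB_true[i] < config.engineB_agreement:
                    b_pep, b_true = peptides[i], True
                else:
                    continue
            else:
                if uB_false[i] < config.engineB_false_overlap:
                    b_pep, b_true = peptides[i], False
                elif uB_false[i] < config.engineB_false_overlap + config.engineB_false_other:
                    b_pep, b_true = alt_peptides[i], False
                else:
                    continue
            rowsB.append(
                PsmRecord(
                    spectrum_key=key,
                    peptide=b_pep,
                    charge=int(charges[i]),
                    engine_score=float(engineB_score[i]),
                    protein_ids=(acc,),
                    is_decoy=False,
                    group=group,
                )
            )
            truth[(key, Engine.engineB.value)] = b_true

    return LabeledPsmSet(
        psms_engineA=PsmTable(rows=rowsA, engine=Engine.engineA, source_path="<synthetic>"),
        psms_engineB=PsmTable(rows=rowsB, engine=Engine.engineB, source_path="<synthetic>"),
        truth=truth,
    )


def simulate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (200, 1500),
    seed: int = 0,
    zero_expression_fraction: float = 0.2,
    n_prob: float = 0.0,
) -> tuple[list[FastaEntry], ExpressionTable]:
    """Random transcripts with log-normal FPKM values.

    Lengths are uniform over ``length_range`` (>= 30 nt); a fraction of
    transcripts gets expression exactly 0 (not detected) and the rest
    log-normal values (median ~e, heavy right tail), so FPKM cutoffs
    0/2/5/10 each drop part of the set.  ``n_prob`` injects ambiguous N
    bases.
    """
    if length_range[0] < 30:
        raise ValueError("transcript lengths must be >= 30 nt")
    rng = np.random.default_rng(seed)
    entries: list[FastaEntry] = []
    expr: dict[str, tuple[str, float, str]] = {}
    for i in range(n_transcripts):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _NT[rng.integers(0, 4, size=length)]
        if n_prob > 0:
            mask = rng.random(length) < n_prob
            seq = np.where(mask, np.bytes_(b"N"), seq)
        tid = f"TX{i:05d}"
        entries.append(
            FastaEntry(accession=tid, description=tid, sequence=seq.tobytes().decode())
        )
        if rng.random() < zero_expression_fraction:
            value = 0.0
        else:
            value = float(rng.lognormal(mean=1.0, sigma=1.5))
        expr[tid] = (f"G{i:05d}", value, "FPKM")
    return entries, ExpressionTable(entries=expr)


def simulate_proteome_with_peptides(
    n_proteins: int,
    shared_peptide_plan: dict[str, set[str]] | None = None,
    seed: int = 0,
    peptide_length: int = 9,
    flank_length: int = 30,
) -> tuple[list[FastaEntry], dict[str, set[str]]]:
    """Proteins containing planted peptides with a known sharing structure.

    ``shared_peptide_plan`` maps accession -> set of peptide *names*; every
    named peptide is realised as one random sequence and embedded (with
    random flanks) in each protein that plans it.  Returns the FASTA
    entries and the realised map peptide sequence -> set of accessions.
    Without a plan, each protein gets one private peptide.
    """
    rng = np.random.default_rng(seed)
    if shared_peptide_plan is None:
        shared_peptide_plan = {f"P{i:04d}": {f"pep{i}"} for i in range(n_proteins)}
    names = sorted({p for peps in shared_peptide_plan.values() for p in peps})
    realised = dict(zip(names, _random_peptides(rng, len(names), peptide_length)))
    entries: list[FastaEntry] = []
    peptide_map: dict[str, set[str]] = {realised[n]: set() for n in names}
    for acc in sorted(shared_peptide_plan):
        parts = []
        for name in sorted(shared_peptide_plan[acc]):
            parts.append(_random_peptides(rng, 1, flank_length)[0])
            parts.append(realised[name])
            peptide_map[realised[name]].add(acc)
        parts.append(_random_peptides(rng, 1, flank_length)[0])
        entries.append(
            FastaEntry(accession=acc, description=acc, sequence="".join(parts))
        )
    return entries, peptide_map


def simulate_annotations(
    n: int,
    seed: int = 0,
    slope: float = 1.8,
    intercept: float = 5.0,
    noise_sd: float = 1.0,
    binder_fraction_true: float = 0.95,
) -> list[PeptideAnnotation]:
    """Peptide annotations with RT linear in HI plus Gaussian noise.

    Binder p-values are drawn uniformly below 0.05 for the nominal binder
    fraction and uniformly above it otherwise.
    """
    rng = np.random.default_rng(seed)
    peptides = _random_peptides(rng, n)
    hi = rng.uniform(5.0, 45.0, n)
    rt = intercept + slope * hi + rng.normal(0, noise_sd, n)
    binder = rng.random(n) < binder_fraction_true
    pvals = np.where(
        binder, rng.uniform(0.0, 0.05, n), rng.uniform(0.0500001, 1.0, n)
    )
    return [
        PeptideAnnotation(
            peptide=peptides[i],
            binder_pvalue=float(pvals[i]),
            hi=float(hi[i]),
            rt_mean=float(rt[i]),
        )
        for i in range(n)
    ]


def config_for_total(
    n_total: int, seed: int = 0, **overrides
) -> SimulationConfig:
    """A :class:`SimulationConfig` scaled to roughly ``n_total`` PSMs.

    The stratum split (10% Z1, 60% Z2, 30% Z3plus) mirrors typical charge
    distributions of HLA class-I peptides.
    """
    base = SimulationConfig(
        seed=seed,
        n_psms_per_stratum={
            "Z1": int(0.1 * n_total),
            "Z2": int(0.6 * n_total),
            "Z3plus": int(0.3 * n_total),
        },
    )
    return replace(base, **overrides) if overrides else base
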