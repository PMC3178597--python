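"""Synthetic multi-species datasets and the dummy-sequence robustness experiment.

The generator emulates the statistical structure barcode-gap analysis
assumes: species-level clusters with low conspecific divergence (sigma,
order 0-2%) separated by much larger heterospecific divergence (delta,
order 2-25%), with optional small indels.  Genealogy is a star of stars
— a root, one ancestor per species at Jukes-Cantor branch length
(delta - sigma)/2, and members at sigma/2 below their ancestor — so the
expected pairwise divergence is exactly sigma within species and delta
between species.  Substitutions follow the continuous-time Jukes-Cantor
process (per-site change probability 3/4·(1 - e^(-4t/3))), which K2P
estimation recovers without bias.

The perturbation experiment grafts "dummy" copies of one sequence —
substituted or gapped at 1-20% of its length, gaps random, evenly
spaced, or in one block — back into a dataset and asks whether greedy
alignment-group clustering still places dummy and source together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .grouping import GroupingParams, build_groups
from .io import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MODES = ("SUBS_RANDOM", "GAPS_RANDOM", "GAPS_EVEN", "GAP_BLOCK")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesSimParams:
    n_species: int
    seqs_per_species: int
    seq_length: int = 600
    intra_div: float = 0.005
    inter_div: float = 0.08
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.seqs_per_species < 1 or self.seq_length < 1:
            raise SimulationError("counts and length must be positive")
        if not 0.0 <= self.intra_div < self.inter_div <= 0.75:
            raise SimulationError("require 0 <= intra_div < inter_div <= 0.75")
        if not 0.0 <= self.indel_rate < 0.5:
            raise SimulationError("indel_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class PerturbationSpec:
    mode: str
    divergence: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SimulationError(f"unknown perturbation mode {self.mode!r}")
        if not 0.0 <= self.divergence <= 0.5:
            raise SimulationError("divergence must be in [0, 0.5]")


@dataclass(frozen=True)
class PerturbationResult:
    mode: str
    divergence: float
    co_clustered: bool
    group_id_base: str
    group_id_dummy: str


def _jc_evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch of expected length t substitutions/site."""
    if t <= 0.0:
        return seq.copy()
    p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p_change)
    if hit.size:
        # shift by 1..3 in base space => always a different base, uniformly
        out[hit] = _BASES[(np.searchsorted(_BASES, out[hit]) + rng.integers(1, 4, hit.size)) % 4]
    return out


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0.0:
        return seq
    out: list[int] = []
    for base in seq:
        u = rng.random()
        if u < rate / 2.0:
            continue  # deletion
        if u < rate:
            out.append(rng.choice(_BASES))  # insertion before the base
        out.append(base)
    if not out:
        out = [rng.choice(_BASES)]
    return np.array(out, dtype=np.uint8)


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def simulate_species_dataset(params: SpeciesSimParams) -> tuple[
        list[SequenceRecord], dict[str, str]]:
    """Generate a multi-species dataset; returns (records, id -> species labels)."""
    rng = np.random.default_rng(params.seed)
    root = rng.choice(_BASES, size=params.seq_length)
    ancestor_branch = (params.inter_div - params.intra_div) / 2.0
    member_branch = params.intra_div / 2.0
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for s in range(params.n_species):
        species = f"species{s + 1:02d}"
        ancestor = _jc_evolve(root, ancestor_branch, rng)
        for m in range(params.seqs_per_species):
            seq = _jc_evolve(ancestor, member_branch, rng)
            seq = _apply_indels(seq, params.indel_rate, rng)
            seq_id = f"sp{s + 1:02d}_{m + 1:02d}"
            records.append(SequenceRecord(id=seq_id, residues=_to_str(seq),
                                          species=species))
            labels[seq_id] = species
    return records, labels


def perturb(base: SequenceRecord, spec: PerturbationSpec) -> SequenceRecord:
    """Dummy copy of ``base`` at the requested edit divergence.

    Divergence counts edit operations relative to the base length:
    SUBS_RANDOM substitutes round(div*L) distinct positions; GAPS_RANDOM
    inserts that many single bases at random positions; GAPS_EVEN inserts
    one base after every ceil(1/div)-th position; GAP_BLOCK inserts one
    contiguous block of round(div*L) bases at a random position.
    """
    rng = np.random.default_rng(spec.seed)
    seq = np.frombuffer(base.residues.encode(), dtype=np.uint8).copy()
    L = seq.size
    count = round(spec.divergence * L)
    new_id = f"{base.id}_dummy"
    if spec.divergence == 0.0:
        return replace(base, id=new_id)
    if spec.mode == "SUBS_RANDOM":
        pos = rng.choice(L, size=count, replace=False)
        seq[pos] = _BASES[(np.searchsorted(_BASES, seq[pos]) + rng.integers(1, 4, count)) % 4]
    elif spec.mode == "GAPS_RANDOM":
        for _ in range(count):
            at = int(rng.integers(0, seq.size + 1))
            seq = np.insert(seq, at, rng.choice(_BASES))
    elif spec.mode == "GAPS_EVEN":
        spacing = math.ceil(1.0 / spec.divergence)
        pieces = []
        for start in range(0, L, spacing):
            chunk = seq[start:start + spacing]
            pieces.append(chunk)
            if chunk.size == spacing:
                pieces.append(np.array([rng.choice(_BASES)], dtype=np.uint8))
        seq = np.concatenate(pieces)
    elif spec.mode == "GAP_BLOCK":
        at = int(rng.integers(0, L + 1))
        block = rng.choice(_BASES, size=count)
        seq = np.concatenate([seq[:at], block, seq[at:]])
    return replace(base, id=new_id, residues=_to_str(seq))


def robustness_experiment(records: list[SequenceRecord], base_id: str,
                          grid: list[PerturbationSpec],
                          params: GroupingParams = GroupingParams()
                          ) -> list[PerturbationResult]:
    """Re-cluster the dataset with one dummy per grid point.

    For every perturbation spec the dummy sequence is appended, groups
    rebuilt from scratch, and the result records whether dummy and source
    landed in the same alignment group.
    """
    by_id = {r.id: r for r in records}
    if base_id not in by_id:
        raise SimulationError(f"base sequence {base_id!r} not in dataset")
    base = by_id[base_id]
    results = []
    for spec in grid:
        dummy = perturb(base, spec)
        groups = build_groups(list(records) + [dummy], params, compute_msa=False)
        loc = {rid: g.group_id for g in groups for rid in g.member_ids}
        results.append(PerturbationResult(
            mode=spec.mode,
            divergence=spec.divergence,
            co_clustered=loc[base_id] == loc[dummy.id],
            group_id_base=loc[base_id],
            group_id_dummy=loc[dummy.id],
        ))
    return results


def default_grid(seed: int = 0, divergences: list[float] | None = None
                 ) -> list[PerturbationSpec]:
    """The full 4-mode x 1-20% experiment grid, one sub-seed per cell."""
    if divergences is None:
        divergences = [d / 100.0 for d in range(1, 21)]
    grid = []
    for m_idx, mode in enumerate(MODES):
        for d_idx, div in enumerate(divergences):
            grid.append(PerturbationSpec(
                mode=mode, divergence=div,
                seed=(seed * 100003 + m_idx * 1009 + d_idx) % (2**31 - 1),
            ))
    return grid
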