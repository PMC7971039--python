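"""Synthetic aptamer-protein interaction datasets with planted signal.

Positive pairs carry two controllable effects: aptamers get a fixed DNA
motif planted at disjoint random slots (``motif_strength`` copies expected
per sequence), and proteins are drawn with a shifted residue composition
(``composition_shift`` log-enrichment, +s/2 on the first ten residues of
ACDEFGHIKLMNPQRSTVWY and -s/2 on the last ten). Negative pairs combine
background aptamers and proteins by random pairing with no duplicate pairs.
With both effects at zero the classes are exchangeable, which is the basis
of the null-calibration acceptance check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .protein import RESIDUES
from .seqio import (
    InteractionDataset,
    NucleotideSequence,
    ProteinSequence,
    write_fasta,
    write_pair_table,
)

NUCLEOTIDES = "ACGT"


@dataclass
class SyntheticParams:
    n_pos: int = 850
    n_neg: int = 2554
    aptamer_length: tuple[int, int] = (20, 80)
    protein_length: tuple[int, int] = (100, 400)
    motif: str = "ACGG"
    motif_strength: float = 0.0
    composition_shift: float = 0.0
    noise: float = 0.0
    seed: int = 0
    # smallest k / largest lambda downstream encoders may use
    kmax: int = 4
    lam: int = 30

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        lo, hi = self.aptamer_length
        if not (0 < lo <= hi):
            raise ValueError(f"invalid aptamer length range {self.aptamer_length}")
        if lo < max(self.kmax, len(self.motif)):
            raise ValueError(
                f"aptamer min length {lo} must be >= kmax={self.kmax} and motif length"
            )
        plo, phi = self.protein_length
        if not (0 < plo <= phi):
            raise ValueError(f"invalid protein length range {self.protein_length}")
        if plo <= self.lam:
            raise ValueError(f"protein min length {plo} must exceed lambda={self.lam}")
        if not set(self.motif) <= set(NUCLEOTIDES):
            raise ValueError(f"motif must be DNA, got {self.motif!r}")
        if not 0 <= self.noise <= 1:
            raise ValueError(f"noise must be a probability, got {self.noise}")
        if self.motif_strength < 0:
            raise ValueError("motif_strength must be >= 0")
        needed = math.ceil(self.motif_strength) * len(self.motif)
        if needed > lo:
            raise ValueError(
                f"cannot plant {self.motif_strength} copies of a {len(self.motif)}-mer "
                f"in sequences of length {lo}"
            )


PRESETS = {
    "null": dict(motif_strength=0.0, composition_shift=0.0),
    "weak": dict(motif_strength=1.0, composition_shift=0.1),
    "strong": dict(motif_strength=3.0, composition_shift=0.5),
}


def preset_params(name: str, **overrides) -> SyntheticParams:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticParams(**kwargs)


def _positive_residue_probs(shift: float) -> np.ndarray:
    logw = np.concatenate([np.full(10, shift / 2.0), np.full(10, -shift / 2.0)])
    w = np.exp(logw)
    return w / w.sum()


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _random_protein(rng: np.random.Generator, length: int, probs: np.ndarray | None = None) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length, p=probs))


def _plant_motif(rng: np.random.Generator, seq: str, motif: str, copies: int) -> str:
    """Overwrite ``copies`` disjoint random slots with the motif."""
    if copies == 0:
        return seq
    k = len(motif)
    starts: list[int] = []
    attempts = 0
    while len(starts) < copies:
        s = int(rng.integers(0, len(seq) - k + 1))
        if all(abs(s - t) >= k for t in starts):
            starts.append(s)
        attempts += 1
        if attempts > 1000 * copies:
            raise ValueError("could not place disjoint motif copies; sequence too short")
    chars = list(seq)
    for s in starts:
        chars[s : s + k] = motif
    return "".join(chars)


def _n_copies(rng: np.random.Generator, strength: float) -> int:
    whole = int(strength)
    frac = strength - whole
    return whole + (1 if frac > 0 and rng.random() < frac else 0)


def generate_dataset(params: SyntheticParams) -> InteractionDataset:
    """Generate a labelled dataset; byte-reproducible under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    pos_probs = _positive_residue_probs(params.composition_shift)

    aptamers: dict[str, NucleotideSequence] = {}
    proteins: dict[str, ProteinSequence] = {}
    pairs: list[tuple[str, str, int]] = []

    alo, ahi = params.aptamer_length
    plo, phi = params.protein_length

    for i in range(params.n_pos):
        apt_id, prot_id = f"apt_p{i:05d}", f"prot_p{i:05d}"
        length = int(rng.integers(alo, ahi + 1))
        seq = _random_dna(rng, length)
        seq = _plant_motif(rng, seq, params.motif, _n_copies(rng, params.motif_strength))
        aptamers[apt_id] = NucleotideSequence(id=apt_id, residues=seq)
        plen = int(rng.integers(plo, phi + 1))
        proteins[prot_id] = ProteinSequence(
            id=prot_id, residues=_random_protein(rng, plen, pos_probs)
        )
        pairs.append((apt_id, prot_id, 1))

    # every negative pair gets fresh background sequences: if sequences were
    # shared across pairs, a classifier could memorize them across CV folds
    # and beat chance even with zero planted signal
    for i in range(params.n_neg):
        apt_id, prot_id = f"apt_n{i:05d}", f"prot_n{i:05d}"
        length = int(rng.integers(alo, ahi + 1))
        aptamers[apt_id] = NucleotideSequence(id=apt_id, residues=_random_dna(rng, length))
        plen = int(rng.integers(plo, phi + 1))
        proteins[prot_id] = ProteinSequence(id=prot_id, residues=_random_protein(rng, plen))
        pairs.append((apt_id, prot_id, 0))

    if params.noise > 0:
        flips = rng.random(len(pairs)) < params.noise
        pairs = [
            (a, p, 1 - label if flip else label)
            for (a, p, label), flip in zip(pairs, flips)
        ]

    return InteractionDataset(pairs=pairs, aptamers=aptamers, proteins=proteins)


def generate_files(params: SyntheticParams, outdir: str | Path) -> dict[str, Path]:
    """Write aptamers.fasta, proteins.fasta and pairs.csv; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = generate_dataset(params)
    paths = {
        "aptamers": outdir / "aptamers.fasta",
        "proteins": outdir / "proteins.fasta",
        "pairs": outdir / "pairs.csv",
    }
    write_fasta(paths["aptamers"], [dataset.aptamers[k] for k in sorted(dataset.aptamers)])
    write_fasta(paths["proteins"], [dataset.proteins[k] for k in sorted(dataset.proteins)])
    write_pair_table(paths["pairs"], dataset)
    return paths


def describe_signal(params: SyntheticParams) -> dict:
    """Closed-form expected class differences implied by the parameters.

    ``expected_motif_freq_diff_naive`` is planted copies / window count,
    ignoring the background windows destroyed by overwriting.
    ``expected_motif_freq_diff`` corrects for those: each planted slot
    removes 2k-1 background windows (matching with probability 4^-k) and,
    when the motif can overlap itself at offset d, partially overlapping
    windows regain a 4^-d match chance on each side. Both are averaged over
    the uniform aptamer length range.
    """
    k = len(params.motif)
    m = params.motif_strength
    q = 4.0**-k
    # motif self-overlap (border) structure
    border_gain = sum(
        2 * 4.0**-d
        for d in range(1, k)
        if params.motif[d:] == params.motif[: k - d]
    )
    alo, ahi = params.aptamer_length
    inv_w = float(np.mean([1.0 / (L - k + 1) for L in range(alo, ahi + 1)]))
    naive = m * inv_w
    corrected = m * (1.0 - (2 * k - 1) * q + border_gain) * inv_w

    uniform = np.full(20, 0.05)
    pos = _positive_residue_probs(params.composition_shift)
    return {
        "motif": params.motif,
        "k": k,
        "expected_copies_per_positive": m,
        "expected_motif_freq_diff_naive": naive,
        "expected_motif_freq_diff": corrected,
        "expected_aac_positive": pos,
        "expected_aac_negative": uniform,
        "expected_aac_shift": pos - uniform,
    }
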