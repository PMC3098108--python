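"""Synthetic HP/MP-like ortholog pairs and mutant series.

The generator emulates the compositional structure of hyperthermophilic /
mesophilic ortholog pair collections without any real sequence data:

* MP sequences are i.i.d. residue strings drawn from the published mean
  mesophilic amino-acid composition, with lengths uniform in 50-600.
* The HP ortholog of an MP sequence is produced by substituting a bounded
  fraction of positions (default one half) with residues drawn from a
  replacement distribution chosen so that the *expected* HP composition
  equals MP composition plus the published HP-minus-MP composition shift
  (Lys and Glu up, Gln/Thr/Ala/His/Ser/Asp/Gly down, most others near
  neutral).  Orthologs are equal-length by default, ungapped identity is at
  least 1 - substitution fraction, and the identity floor (default 0.30)
  and maximum length-difference fraction (default 0.05) of real ortholog
  screens are enforced.

Sequences are i.i.d. at the residue level: no positional conservation,
domain structure, or phylogeny.  That is sufficient for exercising a
composition-driven scoring pipeline, and nothing more.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import LabeledPair, ProteinSequence, write_fasta, write_pair_table
from .tables import STANDARD_AA

#: Mean amino-acid composition of mesophilic proteins (published ortholog
#: survey; normalized to sum to 1).
MP_COMPOSITION: dict[str, float] = {
    "S": 0.050, "Q": 0.037, "N": 0.035, "T": 0.055, "C": 0.010,
    "G": 0.079, "A": 0.080, "H": 0.024, "M": 0.026, "Y": 0.027,
    "F": 0.033, "V": 0.082, "L": 0.089, "P": 0.040, "I": 0.066,
    "W": 0.007, "D": 0.057, "E": 0.079, "K": 0.060, "R": 0.055,
}

#: Mean amino-acid composition of hyperthermophilic proteins (same survey).
HP_COMPOSITION: dict[str, float] = {
    "S": 0.044, "Q": 0.019, "N": 0.035, "T": 0.042, "C": 0.009,
    "G": 0.075, "A": 0.066, "H": 0.017, "M": 0.024, "Y": 0.033,
    "F": 0.038, "V": 0.086, "L": 0.089, "P": 0.041, "I": 0.077,
    "W": 0.008, "D": 0.050, "E": 0.097, "K": 0.091, "R": 0.056,
}

#: Published HP - MP composition differences, the default bias map.
DEFAULT_BIAS: dict[str, float] = {
    aa: HP_COMPOSITION[aa] - MP_COMPOSITION[aa] for aa in STANDARD_AA
}


class GenerationError(ValueError):
    """Generator parameters are mutually inconsistent."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic ortholog-pair generator."""

    n_pairs: int = 540
    min_length: int = 50
    max_length: int = 600
    base_composition: dict[str, float] = field(
        default_factory=lambda: dict(MP_COMPOSITION))
    bias: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BIAS))
    substitution_fraction: float = 0.5
    identity_floor: float = 0.30
    max_length_diff_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise GenerationError("n_pairs must be >= 0")
        if not 1 <= self.min_length <= self.max_length:
            raise GenerationError("invalid length range")
        if not 0.0 < self.identity_floor <= 1.0:
            raise GenerationError("identity floor must be in (0, 1]")
        if not 0.0 <= self.substitution_fraction <= 1.0:
            raise GenerationError("substitution fraction must be in [0, 1]")
        comp = self._normalized_base()
        if abs(sum(self.base_composition.values()) - 1.0) > 0.02:
            raise GenerationError("base composition must sum to ~1")
        for aa in STANDARD_AA:
            if comp[aa] + self.bias.get(aa, 0.0) < -1e-12:
                raise GenerationError(f"bias drives composition of {aa!r} below 0")
        if 1.0 - self.substitution_fraction < self.identity_floor:
            raise GenerationError(
                "substitution fraction incompatible with identity floor")

    def _normalized_base(self) -> dict[str, float]:
        tot = sum(self.base_composition.values())
        return {aa: self.base_composition.get(aa, 0.0) / tot for aa in STANDARD_AA}

    def target_composition(self) -> dict[str, float]:
        """Base composition plus bias, renormalized."""
        base = self._normalized_base()
        raw = {aa: max(base[aa] + self.bias.get(aa, 0.0), 0.0) for aa in STANDARD_AA}
        tot = sum(raw.values())
        return {aa: v / tot for aa, v in raw.items()}

    def replacement_composition(self) -> dict[str, float]:
        """Distribution for substituted positions.

        Solves target = (1-f)*base + f*repl for the replacement
        distribution, clipping at zero; with the default fraction of 0.5
        and the published shift no clipping occurs, so the expected HP
        composition matches the target exactly.
        """
        f = self.substitution_fraction
        if f == 0.0:
            raise GenerationError("substitution fraction 0 admits no replacement draw")
        base = self._normalized_base()
        target = self.target_composition()
        raw = {aa: target[aa] - (1.0 - f) * base[aa] for aa in STANDARD_AA}
        clipped = {aa: max(v, 0.0) for aa, v in raw.items()}
        lost = sum(v for v in raw.values() if v < 0.0)
        if lost < -0.05 * f:
            raise GenerationError(
                "bias too strong for the substitution fraction: replacement "
                "distribution would need negative mass; raise the fraction")
        tot = sum(clipped.values())
        return {aa: v / tot for aa, v in clipped.items()}


def _draw(composition: dict[str, float], length: int, rng: np.random.Generator) -> str:
    aas = np.array(list(STANDARD_AA))
    p = np.array([composition[a] for a in STANDARD_AA], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(aas, size=length, p=p))


def identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Ungapped position-wise identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("ungapped identity requires equal lengths")
    same = sum(1 for x, y in zip(a.residues, b.residues) if x == y)
    return same / len(a)


def sample_mp_sequence(
    spec: GeneratorSpec, rng: np.random.Generator, seq_id: str = "mp"
) -> ProteinSequence:
    """Draw one mesophile-like sequence: i.i.d. residues from the base
    composition, length uniform over the configured range."""
    length = int(rng.integers(spec.min_length, spec.max_length + 1))
    return ProteinSequence(id=seq_id, residues=_draw(spec._normalized_base(), length, rng))


def derive_hp_ortholog(
    mp: ProteinSequence,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    seq_id: str = "hp",
) -> ProteinSequence:
    """Derive a hyperthermophile-like ortholog by biased substitution.

    A fraction ``spec.substitution_fraction`` of positions (chosen without
    replacement) is redrawn from the replacement distribution; the rest are
    conserved, so identity >= 1 - fraction >= the identity floor.  Lengths
    are equal by construction.
    """
    n = len(mp)
    k = int(round(spec.substitution_fraction * n))
    positions = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
    repl = spec.replacement_composition() if k else None
    residues = list(mp.residues)
    if k:
        aas = np.array(list(STANDARD_AA))
        p = np.array([repl[a] for a in STANDARD_AA], dtype=float)
        p = p / p.sum()
        new = rng.choice(aas, size=k, p=p)
        for pos, aa in zip(positions, new):
            residues[pos] = aa
    hp = ProteinSequence(id=seq_id, residues="".join(residues))
    if identity(mp, hp) < spec.identity_floor:
        raise GenerationError("generated pair fell below the identity floor")
    return hp


@dataclass(frozen=True)
class SyntheticDataset:
    pairs: tuple[LabeledPair, ...]
    truth: pd.DataFrame  # per-pair record of the applied shifts

    def write(self, fasta_path, pair_table_path, truth_path) -> None:
        seqs = []
        for p in self.pairs:
            seqs.extend([p.stable, p.other])
        write_fasta(fasta_path, seqs)
        write_pair_table(pair_table_path, self.pairs)
        self.truth.to_csv(truth_path, sep="\t", index=False)


def generate_dataset(spec: GeneratorSpec) -> SyntheticDataset:
    """Generate ``spec.n_pairs`` labeled (HP-like, MP-like) ortholog pairs.

    Deterministic given ``spec.seed``.  The truth table records, per pair,
    the sequence ids, length, realized identity, and the shifted residues
    (those with non-zero bias), so downstream tests can check recovery
    against what was actually injected.
    """
    rng = np.random.default_rng(spec.seed)
    shifted = ",".join(sorted(aa for aa, v in spec.bias.items() if v != 0.0))
    pairs: list[LabeledPair] = []
    rows = []
    for i in range(spec.n_pairs):
        mp = sample_mp_sequence(spec, rng, seq_id=f"mp{i:04d}")
        hp = derive_hp_ortholog(mp, spec, rng, seq_id=f"hp{i:04d}")
        pairs.append(LabeledPair(stable=hp, other=mp))
        rows.append({
            "stable_id": hp.id,
            "other_id": mp.id,
            "length": len(mp),
            "identity": identity(mp, hp),
            "shifted_residues": shifted,
        })
    truth = pd.DataFrame(rows, columns=[
        "stable_id", "other_id", "length", "identity", "shifted_residues"])
    return SyntheticDataset(pairs=tuple(pairs), truth=truth)


def mutant_series(
    wildtype: ProteinSequence,
    n_mutants: int,
    spec: GeneratorSpec,
    rng: np.random.Generator,
) -> list[ProteinSequence]:
    """A wild type plus a cumulative series of stabilizing mutants.

    One full set of biased substitutions (fraction, positions, and
    replacement residues as in :func:`derive_hp_ortholog`) is drawn once;
    mutant i carries the first i/n_mutants share of them.  Each mutant thus
    extends the previous one — the way chimeras and progressive mutant
    series are built — and the true stability order is the list order
    (wild type first, fully substituted mutant last).
    """
    if n_mutants < 1:
        raise GenerationError("need at least one mutant")
    n = len(wildtype)
    k = int(round(spec.substitution_fraction * n))
    positions = rng.permutation(n)[:k]
    repl = spec.replacement_composition()
    aas = np.array(list(STANDARD_AA))
    p = np.array([repl[a] for a in STANDARD_AA], dtype=float)
    replacements = rng.choice(aas, size=k, p=p / p.sum())
    out = [wildtype]
    residues = list(wildtype.residues)
    cut_prev = 0
    for i in range(1, n_mutants + 1):
        cut = int(round(k * i / n_mutants))
        for pos, aa in zip(positions[cut_prev:cut], replacements[cut_prev:cut]):
            residues[pos] = aa
        cut_prev = cut
        out.append(ProteinSequence(f"{wildtype.id}_mut{i}", "".join(residues)))
    return out
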