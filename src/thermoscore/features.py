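"""Sequence-derived feature computation.

For a protein sequence this module computes the full set of non-predicted
features used by the thermostability scoring model: length, per-amino-acid
counts and compositions, charge statistics, residue-class counts and
fractions, side-chain hydrogen-bonding capacity, sulfur content, mean
aqueous solubility, mean maximum solvent-accessible surface area (the
``ASA`` scoring feature), isoelectric point (whole chain and mean residue),
instability index and class, aliphatic index, and GRAVY.

Compositions are normalized by ``L_std``, the number of standard residues:
ambiguity codes (B, J, X, Z, U, O) carry no class membership and are
excluded from both numerator and denominator, while the ``L`` feature
reports the full chain length.

Residue-class definitions and every per-residue property table live in a
:class:`ResidueClassConfig`, so alternative conventions (e.g. His counted
as positive) are one config object away.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from . import tables
from .seqio import ProteinSequence
from .tables import STANDARD_AA


class FeatureError(ValueError):
    """Feature computation impossible for this input (e.g. empty sequence)."""


@dataclass(frozen=True)
class ResidueClassConfig:
    """Residue-class sets and per-residue property tables.

    Every set must be a subset of the 20 standard residues and every table
    must cover all 20.  Defaults are the published tables shipped in
    :mod:`thermoscore.tables`.
    """

    positive: frozenset[str] = tables.POSITIVE
    negative: frozenset[str] = tables.NEGATIVE
    small: frozenset[str] = tables.SMALL
    tiny: frozenset[str] = tables.TINY
    aromatic: frozenset[str] = tables.AROMATIC
    aliphatic: frozenset[str] = tables.ALIPHATIC
    hydrophobic: frozenset[str] = tables.HYDROPHOBIC
    polar: frozenset[str] = tables.POLAR
    hbond_sidechain: frozenset[str] = tables.HBOND_SIDECHAIN
    max_asa: dict[str, float] = field(default_factory=lambda: dict(tables.MAX_ASA))
    solubility: dict[str, float] = field(default_factory=lambda: dict(tables.SOLUBILITY))
    kd_hydropathy: dict[str, float] = field(default_factory=lambda: dict(tables.KD_HYDROPATHY))
    pk_sidechain: dict[str, float] = field(default_factory=lambda: dict(tables.PK_SIDECHAIN))
    pk_nterm: float = tables.PK_NTERM
    pk_cterm: float = tables.PK_CTERM
    residue_pi: dict[str, float] = field(default_factory=lambda: dict(tables.RESIDUE_PI))
    instability_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(r) for a, r in tables.DIPEPTIDE_INSTABILITY.items()}
    )
    instability_threshold: float = 40.0

    def __post_init__(self) -> None:
        std = set(STANDARD_AA)
        for name in ("positive", "negative", "small", "tiny", "aromatic",
                     "aliphatic", "hydrophobic", "polar", "hbond_sidechain"):
            if not set(getattr(self, name)) <= std:
                raise ValueError(f"residue class {name!r} contains non-standard residues")
        for name in ("max_asa", "solubility", "kd_hydropathy", "residue_pi"):
            if set(getattr(self, name)) < std:
                raise ValueError(f"property table {name!r} does not cover all 20 residues")

    def override(self, **kwargs) -> "ResidueClassConfig":
        """Return a copy with the given fields replaced."""
        sets = {"positive", "negative", "small", "tiny", "aromatic",
                "aliphatic", "hydrophobic", "polar", "hbond_sidechain"}
        clean = {k: (frozenset(v) if k in sets else v) for k, v in kwargs.items()}
        return replace(self, **clean)


DEFAULT_CONFIG = ResidueClassConfig()

#: Ordered names of the residue classes with count/fraction feature pairs.
CLASS_FEATURES = ("small", "tiny", "aromatic", "aliphatic", "hydrophobic", "polar")


def _standard_residues(seq: ProteinSequence) -> str:
    return "".join(c for c in seq.residues if c in STANDARD_AA)


def gravy(seq: ProteinSequence, cfg: ResidueClassConfig = DEFAULT_CONFIG) -> float:
    """Grand average of hydropathy over the standard residues."""
    std = _standard_residues(seq)
    if not std:
        raise FeatureError(f"{seq.id!r}: no standard residues for GRAVY")
    return sum(cfg.kd_hydropathy[c] for c in std) / len(std)


def aliphatic_index(seq: ProteinSequence, cfg: ResidueClassConfig = DEFAULT_CONFIG) -> float:
    """Aliphatic index: 100*(X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu)).

    Mole fractions are relative to the standard-residue count; the 2.9 and
    3.9 coefficients are the standard relative side-chain volumes of Val and
    Ile/Leu with respect to Ala.
    """
    std = _standard_residues(seq)
    if not std:
        raise FeatureError(f"{seq.id!r}: no standard residues for aliphatic index")
    n = len(std)
    c = Counter(std)
    return 100.0 * (c["A"] / n + 2.9 * c["V"] / n + 3.9 * (c["I"] / n + c["L"] / n))


def instability_index(
    seq: ProteinSequence, cfg: ResidueClassConfig = DEFAULT_CONFIG
) -> tuple[float, str]:
    """Dipeptide-weight instability index and its stability class.

    II = (10/L) * sum of DIWV(res_i, res_{i+1}) over consecutive standard
    residue pairs; class is "stable" strictly below the threshold (default
    40) and "unstable" at or above it.
    """
    res = seq.residues
    if len(res) < 2:
        raise FeatureError(f"{seq.id!r}: instability index needs length >= 2")
    total = 0.0
    for a, b in zip(res, res[1:]):
        if a in STANDARD_AA and b in STANDARD_AA:
            total += cfg.instability_weights[a][b]
    ii = total * 10.0 / len(res)
    label = "stable" if ii < cfg.instability_threshold else "unstable"
    return ii, label


def _net_charge_at_ph(std: str, ph: float, cfg: ResidueClassConfig) -> float:
    """Henderson-Hasselbalch net charge of the chain at a given pH."""
    counts = Counter(std)
    pos = 10.0 ** (cfg.pk_nterm - ph) / (1.0 + 10.0 ** (cfg.pk_nterm - ph))
    neg = 10.0 ** (ph - cfg.pk_cterm) / (1.0 + 10.0 ** (ph - cfg.pk_cterm))
    for aa, pk in cfg.pk_sidechain.items():
        n = counts.get(aa, 0)
        if not n:
            continue
        if aa in ("K", "R", "H"):
            pos += n * 10.0 ** (pk - ph) / (1.0 + 10.0 ** (pk - ph))
        else:
            neg += n * 10.0 ** (ph - pk) / (1.0 + 10.0 ** (ph - pk))
    return pos - neg


def isoelectric_point(
    seq: ProteinSequence, cfg: ResidueClassConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """Chain pI (bisection on net charge) and mean free-residue pI.

    The chain pI solves net_charge(pH) = 0 to within 0.01 pH units using the
    configured pK set (termini plus the D, E, C, Y, H, K, R side chains).
    The second value is the mean of per-residue free amino acid pI values.
    """
    std = _standard_residues(seq)
    if not std:
        raise FeatureError(f"{seq.id!r}: no standard residues for pI")
    lo, hi = 0.0, 14.0
    # bracket well below the 0.01-pH contract so the net charge at the
    # returned pI is itself ~0 even for charge-dense chains
    while hi - lo > 1e-4:
        mid = (lo + hi) / 2.0
        if _net_charge_at_ph(std, mid, cfg) > 0.0:
            lo = mid
        else:
            hi = mid
    pi = (lo + hi) / 2.0
    pia = sum(cfg.residue_pi[c] for c in std) / len(std)
    return pi, pia


def avg_max_asa(seq: ProteinSequence, cfg: ResidueClassConfig = DEFAULT_CONFIG) -> float:
    """Mean per-residue maximum solvent-accessible surface area (A^2)."""
    std = _standard_residues(seq)
    if not std:
        raise FeatureError(f"{seq.id!r}: no standard residues for ASA")
    return sum(cfg.max_asa[c] for c in std) / len(std)


def avg_solubility(seq: ProteinSequence, cfg: ResidueClassConfig = DEFAULT_CONFIG) -> float:
    """Mean per-residue aqueous solubility (g / 100 g water, 25 C)."""
    std = _standard_residues(seq)
    if not std:
        raise FeatureError(f"{seq.id!r}: no standard residues for solubility")
    return sum(cfg.solubility[c] for c in std) / len(std)


def sulfur_count(seq: ProteinSequence) -> int:
    """Number of sulfur atoms: one per Cys plus one per Met."""
    return seq.residues.count("C") + seq.residues.count("M")


def extract_features(
    seq: ProteinSequence, cfg: ResidueClassConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Compute the full non-predicted feature vector for one sequence.

    Returns a name -> value map.  The instability class is encoded
    numerically (0 = stable, 1 = unstable) so the vector is uniformly
    numeric.  Deterministic: identical inputs give bit-identical output.
    """
    res = seq.residues
    if not res:
        raise FeatureError("empty sequence")
    std = _standard_residues(seq)
    if not std:
        raise FeatureError(f"{seq.id!r}: sequence has no standard residues")
    L = len(res)
    n = len(std)  # L_std: compositional denominator
    counts = Counter(std)

    fv: dict[str, float] = {"L": float(L)}
    for aa in STANDARD_AA:
        fv[f"c_{aa}"] = float(counts.get(aa, 0))
        fv[f"x_{aa}"] = counts.get(aa, 0) / n

    c_pos = sum(counts.get(a, 0) for a in cfg.positive)
    c_neg = sum(counts.get(a, 0) for a in cfg.negative)
    fv["c_pos"] = float(c_pos)
    fv["x_pos"] = c_pos / n
    fv["c_neg"] = float(c_neg)
    fv["x_neg"] = c_neg / n
    fv["c_charge"] = float(c_pos + c_neg)
    fv["x_charge"] = (c_pos + c_neg) / n
    fv["net_charge"] = float(c_pos - c_neg)
    fv["net_charge_per_L"] = (c_pos - c_neg) / n

    for cls in CLASS_FEATURES:
        members = getattr(cfg, cls)
        c = sum(counts.get(a, 0) for a in members)
        fv[f"c_{cls}"] = float(c)
        fv[f"x_{cls}"] = c / n

    c_hb = sum(counts.get(a, 0) for a in cfg.hbond_sidechain)
    fv["c_hbond"] = float(c_hb)
    fv["x_hbond"] = c_hb / n

    fv["sulfur_atoms"] = float(sulfur_count(seq))
    fv["avg_solubility"] = avg_solubility(seq, cfg)
    fv["ASA"] = avg_max_asa(seq, cfg)

    pi, pia = isoelectric_point(seq, cfg)
    fv["pI"] = pi
    fv["pIa"] = pia

    if L >= 2:
        ii, label = instability_index(seq, cfg)
    else:
        ii, label = 0.0, "stable"
    fv["instability_index"] = ii
    fv["instability_class"] = 0.0 if label == "stable" else 1.0

    fv["aliphatic_index"] = aliphatic_index(seq, cfg)
    fv["gravy"] = gravy(seq, cfg)
    return fv


#: Feature names produced by :func:`extract_features`, in output order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    extract_features(ProteinSequence("_probe", STANDARD_AA)).keys()
)

#: Length-normalized / intensive features (candidates for pair scoring).
NORMALIZED_FEATURE_NAMES: tuple[str, ...] = tuple(
    name
    for name in FEATURE_NAMES
    if name.startswith("x_")
    or name in ("net_charge_per_L", "avg_solubility", "ASA", "pI", "pIa",
                "instability_index", "aliphatic_index", "gravy")
)
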