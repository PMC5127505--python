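"""Synthetic saturation-mutagenesis screen generator.

Everything the analysis pipeline consumes can be produced here without any
external download: a wild-type amplicon reference, a programmed single-codon
substitution library with excluded variants and spike-in controls, pooled
selection under class-structured enrichment effects, and paired-end reads
carrying substitution sequencing errors and PCR template-switching chimeras.

The generative model mirrors a pooled yeast plasmid-shuffle screen of the
RNA polymerase II trigger loop (Rpb1 residues 1076-1106): every variant sits
in the transformed pool at some fraction, selection multiplies its frequency
by ``2**effect`` (wild type fixed at effect 0), and sequencing reads the
amplicon back with per-nucleotide substitution noise.  Template switching is
modelled as a single crossover between two independently drawn pool
molecules; emulsion PCR divides the switch rate by a suppression factor.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.stats import binom

__all__ = [
    "AmpliconReference",
    "ExpectedVariantSet",
    "SpikeIn",
    "ClassProfileConfig",
    "SimulatedScreen",
    "ScreenSimulation",
    "make_reference",
    "design_library",
    "make_library",
    "assign_true_effects",
    "simulate_selection",
    "simulate_reads",
    "simulate_screen",
    "write_fastq",
    "reverse_complement",
    "DEFAULT_CONDITIONS",
    "DEFAULT_CLASS_EFFECTS",
    "DEFAULT_CLASS_PROPORTIONS",
    "DEFAULT_SPIKE_INS",
    "LOF_SPIKE_IDS",
    "GOF_SPIKE_IDS",
    "WT_ID",
]

NUCLEOTIDES = "ACGT"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], tuple())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)
AMINO_ACIDS = tuple(sorted(aa for aa in AA_TO_CODONS if aa != "*"))

WT_ID = "WT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


# --------------------------------------------------------------------------
# Reference
# --------------------------------------------------------------------------

# Trigger-loop region, residues 1076-1106.  Residues documented in the
# mutational literature for this region are placed at their positions
# (A1076, Q1078, M1079, T1080, L1081, N1082, H1085, F1086, A1087, G1088,
# V1089, A1090, S1091, K1092, K1093, V1094, S1096, G1097, P1099, L1101,
# E1103); the remaining positions carry arbitrary-but-fixed residues.  The
# nucleotide sequence is a deterministic back-translation, not genomic
# sequence; it is fully overridable via ``make_reference``.
DEFAULT_TL_AA = "ASQMTLNIGHFAGVASKKVTSGNPSLTESLT"
DEFAULT_FIRST_RESIDUE = 1076
DEFAULT_UPSTREAM = "ACGTTGGACCTAGATCCAAG"
DEFAULT_DOWNSTREAM = "GTTCCATGGACGATCTTGCA"


def _codon_for(aa: str) -> str:
    """Deterministic codon choice (alphabetically first) for back-translation."""
    try:
        return AA_TO_CODONS[aa][0]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def _validate_nt(seq: str, what: str) -> None:
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class AmpliconReference:
    """Wild-type coding region of the mutagenised window plus its flanks.

    ``first_residue_number`` anchors codon 1 in protein coordinates, so codon
    index ``i`` (1-based) reports residue ``first_residue_number + i - 1``.
    """

    coding_sequence: str
    upstream_flank: str = DEFAULT_UPSTREAM
    downstream_flank: str = DEFAULT_DOWNSTREAM
    first_residue_number: int = DEFAULT_FIRST_RESIDUE

    def __post_init__(self) -> None:
        _validate_nt(self.coding_sequence, "coding_sequence")
        _validate_nt(self.upstream_flank, "upstream_flank")
        _validate_nt(self.downstream_flank, "downstream_flank")
        if len(self.coding_sequence) % 3 != 0:
            raise ValueError("coding_sequence length must be divisible by 3")
        if not self.coding_sequence:
            raise ValueError("coding_sequence is empty")
        if not self.upstream_flank or not self.downstream_flank:
            raise ValueError("flanks must be non-empty")
        if "*" in self.protein:
            raise ValueError("coding_sequence contains an internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.coding_sequence) // 3

    @property
    def codons(self) -> tuple[str, ...]:
        s = self.coding_sequence
        return tuple(s[i : i + 3] for i in range(0, len(s), 3))

    @property
    def protein(self) -> str:
        return str(Seq(self.coding_sequence).translate())

    @property
    def amplicon(self) -> str:
        return self.upstream_flank + self.coding_sequence + self.downstream_flank

    @property
    def residue_numbers(self) -> tuple[int, ...]:
        return tuple(
            self.first_residue_number + i for i in range(self.n_codons)
        )

    def wt_codon(self, codon_index: int) -> str:
        return self.codons[codon_index - 1]

    def wt_aa(self, codon_index: int) -> str:
        return self.protein[codon_index - 1]

    def residue_of(self, codon_index: int) -> int:
        if not 1 <= codon_index <= self.n_codons:
            raise ValueError(f"codon index {codon_index} out of range")
        return self.first_residue_number + codon_index - 1

    def codon_index_of(self, residue_number: int) -> int:
        idx = residue_number - self.first_residue_number + 1
        if not 1 <= idx <= self.n_codons:
            raise ValueError(f"residue {residue_number} outside amplicon")
        return idx


def make_reference(
    coding_sequence: str | None = None,
    amino_acids: str | None = None,
    upstream_flank: str = DEFAULT_UPSTREAM,
    downstream_flank: str = DEFAULT_DOWNSTREAM,
    first_residue_number: int = DEFAULT_FIRST_RESIDUE,
) -> AmpliconReference:
    """Build a validated amplicon reference.

    Supply either a nucleotide ``coding_sequence`` or an ``amino_acids``
    string (deterministically back-translated).  The default build is the
    31-codon trigger-loop window spanning residues 1076-1106.
    """
    if coding_sequence is None:
        aa = DEFAULT_TL_AA if amino_acids is None else amino_acids
        coding_sequence = "".join(_codon_for(a) for a in aa)
    elif amino_acids is not None:
        ref = AmpliconReference(
            coding_sequence, upstream_flank, downstream_flank, first_residue_number
        )
        if ref.protein != amino_acids:
            raise ValueError("coding_sequence does not translate to amino_acids")
        return ref
    return AmpliconReference(
        coding_sequence, upstream_flank, downstream_flank, first_residue_number
    )


# --------------------------------------------------------------------------
# Programmed library / expected variant set
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeIn:
    """Deliberately added control variant with an intended pool fraction."""

    codon_index: int
    codon: str
    fraction: float


def _best_codon(aa: str, wt_codon: str) -> str:
    """Codon for ``aa`` maximising Hamming distance to the WT codon (ties:
    alphabetical).  Distant codons keep single-nucleotide sequencing errors
    from reaching programmed codons."""
    return max(AA_TO_CODONS[aa], key=lambda c: (hamming(c, wt_codon), c))


_SINGLE_ID_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


def parse_variant_id(variant_id: str) -> tuple[tuple[str, int, str], ...]:
    """Parse e.g. ``"H1085Y"`` or ``"H1085Y,E1103G"`` into
    ``((wt_aa, residue, mut_aa), ...)``."""
    parts = []
    for token in variant_id.split(","):
        m = _SINGLE_ID_RE.match(token)
        if m is None:
            raise ValueError(f"malformed variant id {token!r}")
        parts.append((m.group(1), int(m.group(2)), m.group(3)))
    return tuple(parts)


@dataclass(frozen=True)
class ExpectedVariantSet:
    """The programmed mutant codons, the excluded variants, and spike-ins.

    ``programmed`` is codon-level: ``(codon_index, mutant_codon)`` pairs.
    ``excluded`` is amino-acid-level: ``(residue_number, mutant_aa)`` pairs
    left out of library synthesis.  Spike-ins are excluded variants added
    back to the pool at known fractions as internal controls.
    """

    reference: AmpliconReference
    programmed: frozenset[tuple[int, str]]
    excluded: frozenset[tuple[int, str]] = frozenset()
    spike_ins: tuple[SpikeIn, ...] = ()

    def __post_init__(self) -> None:
        ref = self.reference
        for ci, codon in self.programmed:
            if not 1 <= ci <= ref.n_codons:
                raise ValueError(f"programmed codon index {ci} out of range")
            if codon == ref.wt_codon(ci):
                raise ValueError(
                    f"programmed codon {codon} at index {ci} equals the WT codon"
                )
        for ci, codon in self.programmed:
            key = (ref.residue_of(ci), CODON_TO_AA[codon])
            if key in self.excluded:
                raise ValueError(f"excluded variant {key} present in programmed set")
        total = sum(s.fraction for s in self.spike_ins)
        for s in self.spike_ins:
            if not 0 < s.fraction < 1:
                raise ValueError("spike-in fractions must lie in (0, 1)")
        if total >= 1:
            raise ValueError("spike-in fractions must sum to < 1")

    # -- identity helpers --------------------------------------------------

    def variant_id(self, codon_index: int, codon: str) -> str:
        ref = self.reference
        return (
            f"{ref.wt_aa(codon_index)}{ref.residue_of(codon_index)}"
            f"{CODON_TO_AA[codon]}"
        )

    @property
    def spike_ids(self) -> tuple[str, ...]:
        return tuple(self.variant_id(s.codon_index, s.codon) for s in self.spike_ins)

    def expected_codons(self, codon_index: int) -> frozenset[str]:
        """Whitelist of mutant codons at a position (programmed + spike-ins)."""
        out = {c for ci, c in self.programmed if ci == codon_index}
        out.update(s.codon for s in self.spike_ins if s.codon_index == codon_index)
        return frozenset(out)

    def molecules(self) -> dict[str, tuple[int, str]]:
        """Variant id -> (codon_index, codon) for every pooled single variant."""
        out: dict[str, tuple[int, str]] = {}
        for ci, codon in sorted(self.programmed):
            vid = self.variant_id(ci, codon)
            if vid in out:
                raise ValueError(
                    f"synonymous programmed codons map to the same id {vid}"
                )
            out[vid] = (ci, codon)
        for s in self.spike_ins:
            out[self.variant_id(s.codon_index, s.codon)] = (s.codon_index, s.codon)
        return out


# The five excluded single variants spiked back into the pool as controls.
_SPIKE_SPECS = (("H", 1085, "Y"), ("H", 1085, "Q"), ("F", 1086, "S"),
                ("G", 1097, "D"), ("E", 1103, "G"))
LOF_SPIKE_IDS = ("H1085Y", "H1085Q", "F1086S")
GOF_SPIKE_IDS = ("G1097D", "E1103G")
DEFAULT_SPIKE_FRACTION = 0.005
DEFAULT_SPIKE_INS = tuple(
    (res, aa) for _, res, aa in _SPIKE_SPECS
)
DEFAULT_EXCLUDED = frozenset((res, aa) for _, res, aa in _SPIKE_SPECS)


def design_library(
    ref: AmpliconReference,
    excluded: frozenset[tuple[int, str]] | None = None,
    spike_ins: tuple[tuple[int, str], ...] | None = None,
    spike_fraction: float = DEFAULT_SPIKE_FRACTION,
    min_codon_hamming: int = 1,
) -> ExpectedVariantSet:
    """Design the programmed substitution library.

    One mutant codon per (position, alternative amino acid), chosen to
    maximise Hamming distance from the WT codon; excluded variants are left
    out of synthesis; spike-ins (``(residue_number, mutant_aa)`` pairs) are
    added with ``spike_fraction`` each.  ``min_codon_hamming`` drops target
    substitutions whose best codon is closer than that to the WT codon.
    """
    if excluded is None:
        excluded = DEFAULT_EXCLUDED
    if spike_ins is None:
        spike_ins = DEFAULT_SPIKE_INS
    programmed = set()
    for ci in range(1, ref.n_codons + 1):
        wt_codon = ref.wt_codon(ci)
        wt_aa = ref.wt_aa(ci)
        res = ref.residue_of(ci)
        for aa in AMINO_ACIDS:
            if aa == wt_aa or (res, aa) in excluded:
                continue
            codon = _best_codon(aa, wt_codon)
            if hamming(codon, wt_codon) < min_codon_hamming:
                continue
            programmed.add((ci, codon))
    spikes = []
    for res, aa in spike_ins:
        ci = ref.codon_index_of(res)
        codon = _best_codon(aa, ref.wt_codon(ci))
        spikes.append(SpikeIn(ci, codon, spike_fraction))
    return ExpectedVariantSet(
        reference=ref,
        programmed=frozenset(programmed),
        excluded=frozenset(excluded),
        spike_ins=tuple(spikes),
    )


def make_library(
    evs: ExpectedVariantSet,
    wt_fraction: float = 0.10,
    mode: str = "uniform",
    seed: int | np.random.Generator = 0,
    dirichlet_alpha: float = 5.0,
) -> pd.Series:
    """Pool fractions for every pooled variant (WT holds the remainder).

    ``uniform`` splits the non-WT, non-spike mass evenly across programmed
    variants; ``dirichlet`` draws the split from a symmetric Dirichlet to
    emulate synthesis unevenness.  Excluded, non-spiked variants are simply
    absent (fraction 0).
    """
    if not 0 < wt_fraction < 1:
        raise ValueError("WT fraction must lie in (0, 1)")
    if mode not in ("uniform", "dirichlet"):
        raise ValueError(f"unknown library mode {mode!r}")
    molecules = evs.molecules()
    spike_ids = set(evs.spike_ids)
    programmed_ids = [v for v in molecules if v not in spike_ids]
    spike_total = sum(s.fraction for s in evs.spike_ins)
    mass = 1.0 - wt_fraction - spike_total
    if mass <= 0:
        raise ValueError("WT and spike-in fractions leave no mass for the library")
    if mode == "uniform":
        frac = np.full(len(programmed_ids), mass / len(programmed_ids))
    else:
        rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
        frac = rng.dirichlet(np.full(len(programmed_ids), dirichlet_alpha)) * mass
    fractions = pd.Series(frac, index=programmed_ids, dtype=float)
    for s, vid in zip(evs.spike_ins, evs.spike_ids):
        fractions[vid] = s.fraction
    return fractions.sort_index()


# --------------------------------------------------------------------------
# Class-structured true effects
# --------------------------------------------------------------------------

DEFAULT_CONDITIONS = (
    "Gal", "MPA", "SC-Lys", "Mn5", "Mn15", "Caffeine", "Hydroxyurea",
    "Formamide", "Cycloheximide", "NaOH", "NaCl", "Ethanol", "HCl", "Benomyl",
)

# Mean log2 enrichment per class x condition.  Nonzero entries carry only
# signs the screen reports: all three classes are Gal^R (Class 1 strongly,
# the others weakly); Class 1 (loss of function) is formamide-hypersensitive
# with slight MPA resistance and Mn resistance; Class 2's signature is weak
# Gal^R plus formamide resistance and nothing else; Class 3 (gain of
# function) is Spt^- (enriched on -Lys), MPA^S, and Mn/caffeine/
# cycloheximide hypersensitive.  Conditions the screen found weakly
# allele-specific (NaOH, NaCl, ethanol, HCl, benomyl, hydroxyurea) are left
# neutral.  Magnitudes are simulation parameters: |2| for class-signature
# phenotypes, smaller for phenotypes described as slight/weak.
DEFAULT_CLASS_EFFECTS = pd.DataFrame(
    {
        "Gal":           [2.0, 1.0, 1.0],
        "MPA":           [0.5, 0.0, -2.0],
        "SC-Lys":        [0.0, 0.0, 2.0],
        "Mn5":           [1.0, 0.0, -2.0],
        "Mn15":          [1.0, 0.0, -2.0],
        "Caffeine":      [0.0, 0.0, -2.0],
        "Hydroxyurea":   [0.0, 0.0, 0.0],
        "Formamide":     [-2.0, 2.0, 0.0],
        "Cycloheximide": [0.0, 0.0, -2.0],
        "NaOH":          [0.0, 0.0, 0.0],
        "NaCl":          [0.0, 0.0, 0.0],
        "Ethanol":       [0.0, 0.0, 0.0],
        "HCl":           [0.0, 0.0, 0.0],
        "Benomyl":       [0.0, 0.0, 0.0],
    },
    index=["Class 1", "Class 2", "Class 3"],
)

DEFAULT_CLASS_PROPORTIONS = {
    "Class 1": 0.35,
    "Class 2": 0.25,
    "Class 3": 0.35,
    "neutral": 0.05,
}


@dataclass
class ClassProfileConfig:
    """Configuration of the class-structured enrichment-effect generator."""

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    class_effects: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_CLASS_EFFECTS.copy()
    )
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        missing = set(self.conditions) - set(self.class_effects.columns)
        if missing:
            raise ValueError(f"class_effects lacks conditions {sorted(missing)}")


def assign_true_effects(
    variant_ids: list[str],
    cfg: ClassProfileConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-variant true log2 effects and class labels.

    Spike-in controls are anchored to their known classes (loss-of-function
    spike-ins -> Class 1, gain-of-function -> Class 3); the rest are assigned
    by the configured proportions.  Per-variant, per-condition Gaussian noise
    of sd ``noise_sd`` is added around the class mean (neutral mean is 0).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    names = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[n] for n in names])
    labels = pd.Series(
        rng.choice(names, size=len(variant_ids), p=probs),
        index=variant_ids, name="class",
    )
    for vid in LOF_SPIKE_IDS:
        if vid in labels.index:
            labels[vid] = "Class 1"
    for vid in GOF_SPIKE_IDS:
        if vid in labels.index:
            labels[vid] = "Class 3"
    means = np.zeros((len(variant_ids), len(cfg.conditions)))
    for i, vid in enumerate(variant_ids):
        lab = labels[vid]
        if lab in cfg.class_effects.index:
            means[i] = cfg.class_effects.loc[lab, list(cfg.conditions)].to_numpy()
    effects = means + rng.normal(0.0, cfg.noise_sd, size=means.shape)
    return (
        pd.DataFrame(effects, index=variant_ids, columns=list(cfg.conditions)),
        labels,
    )


# --------------------------------------------------------------------------
# Selection and reads
# --------------------------------------------------------------------------


@dataclass
class SimulatedScreen:
    """Bundle of generative parameters for a single simulated screen."""

    reference: AmpliconReference
    variant_set: ExpectedVariantSet
    pool_fractions: pd.Series
    true_effects: pd.DataFrame
    read_depth: int = 100_000
    pcr_mode: str = "emulsion"
    template_switch_rate: float = 0.01
    error_rate: float = 0.001
    empcr_suppression: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_depth <= 0:
            raise ValueError("read depth must be positive")
        if self.pcr_mode not in ("regular", "emulsion"):
            raise ValueError(f"unknown pcr_mode {self.pcr_mode!r}")
        for name in ("template_switch_rate", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if (self.pool_fractions < 0).any():
            raise ValueError("pool fractions must be >= 0")
        if self.pool_fractions.sum() > 1 + 1e-9:
            raise ValueError("pool fractions must sum to <= 1")


def simulate_selection(
    pool_fractions: pd.Series,
    effects: pd.Series | None,
    depth: int,
    rng: np.random.Generator | int = 0,
) -> pd.Series:
    """Multinomial read counts for one sample.

    Unselected samples (``effects`` None) draw straight from the pool
    fractions.  Selected samples reweight each variant's fraction by
    ``2**effect`` with the WT effect fixed at 0 and renormalise, so the
    phenotype log-ratio of a variant against WT estimates its true effect.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    ids = list(pool_fractions.index)
    frac = pool_fractions.to_numpy(dtype=float)
    wt = 1.0 - frac.sum()
    if wt < -1e-9:
        raise ValueError("pool fractions sum to more than 1")
    wt = max(wt, 0.0)
    weights = np.concatenate([[wt], frac])
    if effects is not None:
        e = effects.reindex(ids).fillna(0.0).to_numpy(dtype=float)
        weights = weights * np.concatenate([[1.0], np.exp2(e)])
    probs = weights / weights.sum()
    counts = rng.multinomial(depth, probs)
    return pd.Series(counts, index=[WT_ID] + ids, name="count")


def _mutant_core(ref: AmpliconReference, subs: tuple[tuple[int, str], ...]) -> str:
    codons = list(ref.codons)
    for ci, codon in subs:
        codons[ci - 1] = codon
    return "".join(codons)


def _truncated_binomial(rng: np.random.Generator, n_draws: int, L: int, p: float) -> np.ndarray:
    """Zero-truncated Binomial(L, p) error counts via inverse-CDF sampling."""
    p0 = binom.cdf(0, L, p)
    u = rng.random(n_draws)
    return binom.ppf(p0 + u * (1.0 - p0), L, p).astype(int)


def simulate_reads(
    counts: pd.Series,
    ref: AmpliconReference,
    evs: ExpectedVariantSet,
    error_rate: float = 0.001,
    template_switch_rate: float = 0.0,
    pcr_mode: str = "emulsion",
    seed: int | np.random.Generator = 0,
    empcr_suppression: float = 2.5,
) -> Counter:
    """Turn per-variant read counts into a multiset of amplicon sequences.

    Returns a ``Counter`` mapping full amplicon sequences (upstream flank +
    coding region + downstream flank) to read multiplicities; both mates of
    a pair carry the same template, so paired FASTQ is a deterministic
    expansion (:func:`write_fastq`).

    With probability ``template_switch_rate`` (divided by
    ``empcr_suppression`` in emulsion mode) a read is a single-crossover
    recombinant of two independently drawn pool molecules: if both are
    single variants at distinct codons the crossover lies between the two
    mutated codons and the chimera carries both substitutions.  Substitution
    sequencing errors hit each amplicon nucleotide independently at
    ``error_rate``.
    """
    if not 0 <= error_rate <= 1 or not 0 <= template_switch_rate <= 1:
        raise ValueError("error and switch rates must lie in [0, 1]")
    if pcr_mode not in ("regular", "emulsion"):
        raise ValueError(f"unknown pcr_mode {pcr_mode!r}")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    p_switch = template_switch_rate
    if pcr_mode == "emulsion":
        p_switch /= empcr_suppression

    molecules = evs.molecules()
    ids = list(counts.index)
    subs_of: dict[str, tuple[tuple[int, str], ...]] = {}
    for vid in ids:
        if vid == WT_ID:
            subs_of[vid] = ()
        elif vid in molecules:
            subs_of[vid] = (molecules[vid],)
        else:  # composite id, e.g. a pre-existing double
            subs = []
            for wt_aa, res, mut_aa in parse_variant_id(vid):
                ci = ref.codon_index_of(res)
                codon = _best_codon(mut_aa, ref.wt_codon(ci))
                subs.append((ci, codon))
            subs_of[vid] = tuple(subs)

    vec = counts.to_numpy(dtype=int).copy()
    depth = int(vec.sum())
    core_counts: Counter[tuple[tuple[int, str], ...]] = Counter()

    # template switching: replace n_switch reads with chimeras
    n_switch = rng.binomial(depth, p_switch) if p_switch > 0 else 0
    if n_switch > 0:
        removed = rng.multivariate_hypergeometric(vec, n_switch)
        vec = vec - removed
        freqs = counts.to_numpy(dtype=float) / depth
        a_idx = rng.choice(len(ids), size=n_switch, p=freqs)
        b_idx = rng.choice(len(ids), size=n_switch, p=freqs)
        pair_counts = Counter(zip(a_idx.tolist(), b_idx.tolist()))
        for (ai, bi), k in pair_counts.items():
            sa, sb = subs_of[ids[ai]], subs_of[ids[bi]]
            pos_a = {ci for ci, _ in sa}
            if sa and sb and not pos_a & {ci for ci, _ in sb}:
                chimera = tuple(sorted(sa + sb))
            else:
                chimera = sa
            core_counts[chimera] += k
    for vid, k in zip(ids, vec.tolist()):
        if k:
            core_counts[subs_of[vid]] += k

    # sequencing errors, applied to the whole amplicon (flanks included)
    up, down = ref.upstream_flank, ref.downstream_flank
    L = len(ref.amplicon)
    reads: Counter[str] = Counter()
    p_any = 1.0 - (1.0 - error_rate) ** L if error_rate > 0 else 0.0
    for subs, k in sorted(core_counts.items()):
        amplicon = up + _mutant_core(ref, subs) + down
        n_err = rng.binomial(k, p_any) if p_any > 0 else 0
        if k - n_err:
            reads[amplicon] += k - n_err
        if n_err:
            n_per_read = _truncated_binomial(rng, n_err, L, error_rate)
            for m in n_per_read:
                pos = rng.choice(L, size=int(m), replace=False)
                seq = list(amplicon)
                for p in pos:
                    alts = [b for b in NUCLEOTIDES if b != seq[p]]
                    seq[p] = alts[rng.integers(3)]
                reads["".join(seq)] += 1
    return reads


def write_fastq(
    readset: Counter,
    fastq1,
    fastq2,
    prefix: str = "sim",
) -> int:
    """Expand an amplicon multiset to paired FASTQ (4-line records, Phred+33).

    Mate 1 is the amplicon forward strand, mate 2 its reverse complement;
    qualities are constant.  Output order is deterministic (sorted by
    sequence), so identical inputs give byte-identical files.
    """
    n = 0
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for seq, count in sorted(readset.items()):
            rc = reverse_complement(seq)
            qual = "I" * len(seq)
            for _ in range(count):
                n += 1
                f1.write(f"@{prefix}:{n}/1\n{seq}\n+\n{qual}\n")
                f2.write(f"@{prefix}:{n}/2\n{rc}\n+\n{qual}\n")
    return n


# --------------------------------------------------------------------------
# Whole-screen orchestration
# --------------------------------------------------------------------------


@dataclass
class ScreenSimulation:
    """Everything a simulated screen produced, plus its ground truth."""

    reference: AmpliconReference
    variant_set: ExpectedVariantSet
    pool_fractions: pd.Series
    true_effects: pd.DataFrame
    true_labels: pd.Series
    sample_sheet: pd.DataFrame
    counts: pd.DataFrame  # variant x sample, pre-sequencing truth counts
    readsets: dict[str, Counter] | None


def _sample_name(condition: str, replicate: int) -> str:
    return f"{condition}_rep{replicate}"


def simulate_screen(
    n_variants: int | None = 412,
    conditions: tuple[str, ...] | None = None,
    profile: ClassProfileConfig | None = None,
    true_effects: pd.DataFrame | None = None,
    depth: int = 100_000,
    n_replicates: int = 3,
    wt_fraction: float = 0.10,
    spike_fraction: float = DEFAULT_SPIKE_FRACTION,
    library_mode: str = "uniform",
    error_rate: float = 0.001,
    template_switch_rate: float = 0.01,
    pcr_mode: str = "emulsion",
    empcr_suppression: float = 2.5,
    pool_condition: str = "SC-Leu",
    seed: int = 0,
    make_reads: bool = True,
    reference: AmpliconReference | None = None,
) -> ScreenSimulation:
    """Simulate the full pooled screen.

    One unselected (transformed pool, ``pool_condition``) sample and one
    selected sample per condition are drawn per replicate, each at ``depth``
    reads.  ``n_variants`` subsamples the programmed library to emulate the
    set of variants that survive fitness filtering.  If ``true_effects`` is
    given it overrides the class-profile generator (columns define the
    conditions).
    """
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_lib, rng_fx, rng_sel, rng_reads = rngs

    ref = reference if reference is not None else make_reference()
    evs = design_library(ref, spike_fraction=spike_fraction)
    if n_variants is not None:
        programmed_ids = sorted(evs.molecules().keys() - set(evs.spike_ids))
        if n_variants > len(programmed_ids):
            raise ValueError("n_variants exceeds the designed library size")
        keep = set(
            rng_lib.choice(programmed_ids, size=n_variants, replace=False)
        )
        molecules = evs.molecules()
        evs = ExpectedVariantSet(
            reference=ref,
            programmed=frozenset(molecules[v] for v in keep),
            excluded=evs.excluded,
            spike_ins=evs.spike_ins,
        )
    fractions = make_library(
        evs, wt_fraction=wt_fraction, mode=library_mode, seed=rng_lib
    )
    variant_ids = list(fractions.index)

    if true_effects is None:
        if profile is None:
            profile = ClassProfileConfig(
                conditions=conditions if conditions is not None else DEFAULT_CONDITIONS
            )
        effects, labels = assign_true_effects(variant_ids, profile, rng_fx)
    else:
        effects = true_effects.reindex(variant_ids).fillna(0.0)
        labels = pd.Series("", index=variant_ids, name="class")
    condition_list = list(effects.columns)

    rows = []
    counts = {}
    readsets: dict[str, Counter] | None = {} if make_reads else None
    for rep in range(1, n_replicates + 1):
        plan = [(pool_condition, "unselected", None)] + [
            (c, "selected", effects[c]) for c in condition_list
        ]
        for condition, role, eff in plan:
            sample = _sample_name(condition, rep)
            cnt = simulate_selection(fractions, eff, depth, rng_sel)
            counts[sample] = cnt
            rows.append(
                {"sample": sample, "condition": condition,
                 "replicate": rep, "role": role}
            )
            if make_reads:
                readsets[sample] = simulate_reads(
                    cnt, ref, evs,
                    error_rate=error_rate,
                    template_switch_rate=template_switch_rate,
                    pcr_mode=pcr_mode,
                    seed=rng_reads,
                    empcr_suppression=empcr_suppression,
                )
    sheet = pd.DataFrame(rows).set_index("sample", drop=False)
    count_df = pd.DataFrame(counts).fillna(0).astype(int)
    return ScreenSimulation(
        reference=ref,
        variant_set=evs,
        pool_fractions=fractions,
        true_effects=effects,
        true_labels=labels,
        sample_sheet=sheet,
        counts=count_df,
        readsets=readsets,
    )
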