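"""Codon-normalised amino-acid composition bias toward the Pol II CTD.

The statistic: translate a set of selected RNA sequences in all three
5'->3' reading frames, pool the amino-acid counts, normalise the
frequency of each amino acid by its number of sense codons in the
universal genetic code (so that composition differences are not driven
by codon multiplicity), and measure the Jensen-Shannon divergence (JSD,
base-2 logs, bounded by 1) to the equally codon-normalised composition
of the CTD heptad repeat YSPTSPS. Significance comes from a Monte-Carlo
null: many sets of random RNA sequences of the same lengths, drawn
i.i.d. from genome-wide background nucleotide frequencies, pushed
through the identical pipeline. Similarity to the CTD means a LOW
divergence, so the test is lower-tailed: the empirical p-value is
(m+1)/(n+1) with m the number of null JSDs at or below the observed
one, and a Gaussian lower-tail p-value at z = (observed - mean)/sd is
reported for extrapolation far beyond Monte-Carlo resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from scipy.stats import norm

from .seqcore import (
    AA_INDEX,
    AA_ORDER,
    GeneticCode,
    NucSeq,
    STANDARD_CODE,
    translate,
)

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _codon_to_aa_lookup(code: GeneticCode) -> np.ndarray:
    """64-entry lookup: codon index (16*b0 + 4*b1 + b2) -> aa index, -1 for stop."""
    lut = np.full(64, -1, dtype=np.int64)
    for codon, aa in code.table.items():
        idx = 16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]
        lut[idx] = AA_INDEX[aa] if aa != "*" else -1
    return lut


_CODON2AA = _codon_to_aa_lookup(STANDARD_CODE)

#: codon multiplicities in AA_ORDER
_MULTIPLICITY = np.array(
    [STANDARD_CODE.codon_multiplicity[aa] for aa in AA_ORDER], dtype=float
)


@dataclass(frozen=True)
class AAFreqDist:
    """Frequency vector over the 20 standard amino acids (AA_ORDER index)."""

    freqs: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.shape != (20,):
            raise ValueError("expected a 20-vector of amino-acid frequencies")
        if np.any(f < 0):
            raise ValueError("negative frequency")
        if self.normalized and abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"normalized distribution sums to {f.sum()!r}, not 1")

    @classmethod
    def from_counts(cls, counts: dict[str, float] | np.ndarray) -> "AAFreqDist":
        if isinstance(counts, dict):
            v = np.zeros(20)
            for aa, c in counts.items():
                v[AA_INDEX[aa]] = c
        else:
            v = np.asarray(counts, dtype=float)
        total = v.sum()
        if total <= 0:
            raise ValueError("empty composition: no scorable amino acids")
        return cls(freqs=v / total, normalized=True)

    def as_dict(self) -> dict[str, float]:
        return {aa: float(f) for aa, f in zip(AA_ORDER, self.freqs)}


@dataclass(frozen=True)
class BackgroundModel:
    """Mononucleotide background (A, C, G, T frequencies summing to 1)."""

    base_freqs: tuple[float, float, float, float]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.base_freqs)
        object.__setattr__(self, "base_freqs", f)
        if len(f) != 4 or any(x < 0 for x in f):
            raise ValueError("need 4 non-negative base frequencies (A,C,G,T)")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")

    @classmethod
    def human_genome(cls) -> "BackgroundModel":
        """Genome-wide human mononucleotide frequencies (A/T 29.5%, C/G 20.5%)."""
        return cls(base_freqs=(0.295, 0.205, 0.205, 0.295), source="human genome")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(base_freqs=(0.25, 0.25, 0.25, 0.25), source="uniform")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.base_freqs)


@dataclass
class NullDistribution:
    """Monte-Carlo JSD samples under the random-sequence null."""

    samples: np.ndarray
    n_sets: int
    seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        self.samples = s
        if len(s) != self.n_sets:
            raise ValueError("len(samples) must equal n_sets")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("JSD samples must lie in [0, 1]")
        self.mean = float(s.mean())
        self.sd = float(s.std(ddof=1))


@dataclass(frozen=True)
class BiasTestResult:
    """Observed JSD against the CTD, with Monte-Carlo and Gaussian p-values."""

    observed_jsd: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    p_gaussian: float
    n_sets: int
    z_defined: bool = True


@dataclass(frozen=True)
class CodonUsageProfile:
    """Counts of every codon over all complete codons in all three frames."""

    counts: dict[str, int]
    stop_codon_total: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def aa_frequencies(
    seqs: list[NucSeq],
    frames: tuple[int, ...] = (0, 1, 2),
    weights: list[int] | None = None,
    code: GeneticCode | None = None,
) -> AAFreqDist:
    """Pooled amino-acid frequencies over all sequences and the given frames.

    Stop codons ('*') and N-containing codons ('X') are excluded and the
    vector renormalised. ``weights`` optionally multiplies each
    sequence's contribution (e.g. by read count); the default pools each
    unique sequence once.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    if weights is not None and len(weights) != len(seqs):
        raise ValueError("weights must match sequences one-to-one")
    code = code or STANDARD_CODE
    counts = np.zeros(20)
    for k, s in enumerate(seqs):
        w = 1 if weights is None else weights[k]
        for frame in frames:
            if len(s) - frame < 3:
                continue
            for aa in translate(s, frame, code).seq:
                if aa not in ("*", "X"):
                    counts[AA_INDEX[aa]] += w
    if counts.sum() <= 0:
        raise ValueError("empty composition: no scorable codons")
    return AAFreqDist.from_counts(counts)


def codon_normalize(dist: AAFreqDist, code: GeneticCode | None = None) -> AAFreqDist:
    """Divide each frequency by the amino acid's codon multiplicity, renormalise."""
    if not dist.normalized:
        raise ValueError("input distribution must be normalized")
    if code is None:
        mult = _MULTIPLICITY
    else:
        mult = np.array([code.codon_multiplicity[aa] for aa in AA_ORDER], dtype=float)
    v = dist.freqs / mult
    return AAFreqDist(freqs=v / v.sum(), normalized=True)


def ctd_reference(ctd=None, code: GeneticCode | None = None) -> AAFreqDist:
    """Codon-normalised amino-acid composition of the CTD.

    Default is the consensus heptad YSPTSPS (repetition-invariant, so
    any number of perfect heptads gives the same answer); a full CTD
    ProteinSeq may be supplied instead.
    """
    from .alignment import CTD_HEPTAD  # local import to avoid cycle

    seq = CTD_HEPTAD if ctd is None else ctd.seq
    if not seq:
        raise ValueError("empty CTD sequence")
    counts: dict[str, float] = {}
    for aa in seq:
        if aa not in ("*", "X"):
            counts[aa] = counts.get(aa, 0) + 1
    return codon_normalize(AAFreqDist.from_counts(counts), code)


def jsd(p: AAFreqDist | np.ndarray, q: AAFreqDist | np.ndarray) -> float:
    """Jensen-Shannon divergence with base-2 logs: H(m) - (H(p)+H(q))/2.

    Bounded in [0, 1]; 0 iff the distributions coincide.
    """
    pv = p.freqs if isinstance(p, AAFreqDist) else np.asarray(p, dtype=float)
    qv = q.freqs if isinstance(q, AAFreqDist) else np.asarray(q, dtype=float)
    for v in (pv, qv):
        if abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
            raise ValueError("jsd requires normalized distributions")
    return float(_jsd_rows(pv[None, :], qv)[0])


def _entropy2_rows(rows: np.ndarray) -> np.ndarray:
    """Shannon entropy (base 2) of each row; 0*log0 := 0."""
    return -xlogy(rows, rows).sum(axis=1) / np.log(2)


def _jsd_rows(P: np.ndarray, q: np.ndarray) -> np.ndarray:
    m = 0.5 * (P + q[None, :])
    out = _entropy2_rows(m) - 0.5 * (_entropy2_rows(P) + _entropy2_rows(q[None, :]))
    # clip tiny negative round-off
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Monte-Carlo null
# ---------------------------------------------------------------------------

def _aa_counts_from_bases(bases: np.ndarray, bounds: list[tuple[int, int]]) -> np.ndarray:
    """Three-frame amino-acid counts from concatenated base indices.

    ``bases`` holds 0..3 codes (A,C,G,T) for all sequences laid end to
    end; ``bounds`` gives each sequence's (start, end) slice. Stop
    codons are excluded. Exactly equivalent to translating each
    sequence's three frames and counting (tested against that path).
    """
    counts = np.zeros(20, dtype=np.int64)
    for s, e in bounds:
        b = bases[s:e]
        L = e - s
        for f in (0, 1, 2):
            n = (L - f) // 3
            if n <= 0:
                continue
            c = b[f : f + 3 * n].reshape(n, 3)
            idx = 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]
            aa = _CODON2AA[idx]
            aa = aa[aa >= 0]
            counts += np.bincount(aa, minlength=20)
    return counts


def _null_jsd_batch(
    lengths: list[int],
    bg: BackgroundModel,
    reference: AAFreqDist,
    n_sets: int,
    rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """Vectorised null: JSD of codon-normalised composition per replicate."""
    lengths = list(lengths)
    total = sum(lengths)
    ref = reference.freqs
    # group equal lengths so replicates x sequences vectorise
    from collections import Counter

    groups = sorted(Counter(lengths).items())
    out = np.empty(n_sets)
    done = 0
    cum = np.cumsum(bg.as_array())
    while done < n_sets:
        r = min(chunk, n_sets - done)
        counts = np.zeros((r, 20), dtype=np.int64)
        rep_offset = np.arange(r, dtype=np.int64)[:, None, None] * 20
        for L, k in groups:
            u = rng.random((r, k, L))
            B = np.searchsorted(cum, u).astype(np.int64)
            np.clip(B, 0, 3, out=B)
            for f in (0, 1, 2):
                n = (L - f) // 3
                if n <= 0:
                    continue
                C = B[:, :, f : f + 3 * n].reshape(r, k, n, 3)
                idx = 16 * C[..., 0] + 4 * C[..., 1] + C[..., 2]
                aa = _CODON2AA[idx]
                valid = aa >= 0
                flat = (rep_offset + aa)[valid]
                counts += np.bincount(flat, minlength=r * 20).reshape(r, 20)
        freqs = counts / counts.sum(axis=1, keepdims=True)
        normed = freqs / _MULTIPLICITY[None, :]
        normed /= normed.sum(axis=1, keepdims=True)
        out[done : done + r] = _jsd_rows(normed, ref)
        done += r
    assert total > 0
    return out


def sample_null(
    lengths: list[int],
    bg: BackgroundModel,
    reference: AAFreqDist,
    n_sets: int,
    seed: int,
) -> NullDistribution:
    """Monte-Carlo null distribution of the codon-normalised JSD.

    Each replicate draws one i.i.d. random sequence per observed length
    from the background model, pools three-frame amino-acid counts,
    codon-normalises, and records the JSD against ``reference``.
    Reproducible given ``seed``. ``n_sets`` below 100 is refused (the
    null sd would be unreliable).
    """
    if n_sets < 100:
        raise ValueError("n_sets must be >= 100 for a usable null")
    if not lengths or any(l < 5 for l in lengths):
        raise ValueError("lengths must be non-empty, each >= 5")
    rng = np.random.default_rng(seed)
    samples = _null_jsd_batch(lengths, bg, reference, n_sets, rng)
    return NullDistribution(samples=samples, n_sets=n_sets, seed=seed)


def gaussian_lower_tail_p(z: float) -> float:
    """One-sided lower-tail standard-normal probability at z."""
    return float(norm.cdf(z))


def bias_test(
    observed: list[NucSeq],
    bg: BackgroundModel | None = None,
    reference: AAFreqDist | None = None,
    n_sets: int = 10_000,
    seed: int = 0,
    weights: list[int] | None = None,
) -> BiasTestResult:
    """Test whether a sequence set is compositionally biased toward the CTD.

    Lower-tail by construction: CTD-like composition shows up as a
    divergence SMALLER than random sequences'. Returns the observed
    JSD, z-score against the null, the (m+1)/(n+1) empirical p-value
    with m = #{null <= observed}, and the Gaussian lower-tail p at z.
    """
    bg = bg or BackgroundModel.human_genome()
    reference = reference if reference is not None else ctd_reference()
    obs_dist = codon_normalize(aa_frequencies(observed, weights=weights))
    observed_jsd = jsd(obs_dist, reference)
    null = sample_null([len(s) for s in observed], bg, reference, n_sets, seed)
    m = int(np.sum(null.samples <= observed_jsd))
    p_emp = (m + 1) / (n_sets + 1)
    if null.sd > 0:
        z = (observed_jsd - null.mean) / null.sd
        return BiasTestResult(
            observed_jsd=observed_jsd,
            null_mean=null.mean,
            null_sd=null.sd,
            z=z,
            p_empirical=p_emp,
            p_gaussian=gaussian_lower_tail_p(z),
            n_sets=n_sets,
        )
    return BiasTestResult(
        observed_jsd=observed_jsd,
        null_mean=null.mean,
        null_sd=null.sd,
        z=float("nan"),
        p_empirical=p_emp,
        p_gaussian=float("nan"),
        n_sets=n_sets,
        z_defined=False,
    )


def codon_usage(seqs: list[NucSeq]) -> CodonUsageProfile:
    """Counts of every complete codon in all three 5'->3' frames.

    Frames are taken on the given strand only (the profile of a reverse
    complement differs in general). Stop codons are counted in the
    profile and their total reported separately.
    """
    counts: dict[str, int] = {}
    stop_total = 0
    for s in seqs:
        if len(s) < 5:
            raise ValueError(f"{s.id!r}: too short for three-frame codon usage")
        for f in (0, 1, 2):
            seq = s.seq
            for i in range(f, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                if "N" in codon:
                    continue
                counts[codon] = counts.get(codon, 0) + 1
                if STANDARD_CODE.table[codon] == "*":
                    stop_total += 1
    return CodonUsageProfile(counts=counts, stop_codon_total=stop_total)
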