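"""TCR V(D)J germline rearrangement simulation and repertoire statistics.

Models the sequential assembly of T cell receptor beta and alpha chains in
developing thymocytes, for sizing TCR-sequencing experiments.  The beta
chain rearranges first: V and D segments are drawn uniformly, the J (and
matching C) segment comes from the first J/C cassette on the first attempt
and from the second cassette on a retry, and untemplated nucleotides are
inserted at every junction (Poisson, lambda = 4 by default).  A chain is
productive when some ATG inside the chosen V segment opens a reading frame
that runs, stop-free, through the end of the constant segment.  Under
allelic exclusion a productive beta chain halts further beta rearrangement
and triggers alpha rearrangement (one attempt per allele).  A thymocyte
succeeds only when both chains are productive.

Repertoire-level summaries (segment-usage proportions and Shannon entropy
of CDR3 clonotypes under subsampling) quantify how many cells a
TCR-sequencing experiment must capture to saturate the repertoire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "Segment",
    "GermlineLocus",
    "ChainAttempt",
    "Thymocyte",
    "Repertoire",
    "load_locus_fasta",
    "write_locus_fasta",
    "is_productive",
    "rearrange_chain",
    "simulate_thymocyte",
    "simulate_repertoire",
    "clonotype",
    "shannon_entropy",
    "saturation_stats",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGT")
DEFAULT_INSERTION_LAMBDA = 4.0

Chain = Literal["alpha", "beta"]


class LocusError(ValueError):
    """The germline locus is missing segments required for a rearrangement."""


@dataclass(frozen=True)
class Segment:
    """One germline gene segment."""

    name: str
    chain: Chain
    segtype: Literal["V", "D", "J", "C"]
    cassette: int | None  # 1 or 2 for beta J/C, None otherwise
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"segment {self.name}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"segment {self.name}: non-ACGT characters {sorted(bad)}")


@dataclass
class GermlineLocus:
    """V/D/J/C segment sequences for the alpha and beta TCR chains.

    Beta J and C segments belong to one of two cassettes (J1/C1, J2/C2);
    alpha segments carry no cassette.
    """

    segments: list[Segment]

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        self._index: dict[tuple, list[Segment]] = {}
        for s in self.segments:
            self._index.setdefault((s.chain, s.segtype, s.cassette), []).append(s)
            self._index.setdefault((s.chain, s.segtype, None if s.cassette else "any"), [])

    def get(self, chain: Chain, segtype: str, cassette: int | None = None) -> list[Segment]:
        """Segments of one class; ``cassette=None`` pools both cassettes."""
        if cassette is None:
            return [s for s in self.segments if s.chain == chain and s.segtype == segtype]
        return [
            s
            for s in self.segments
            if s.chain == chain and s.segtype == segtype and s.cassette == cassette
        ]

    def validate_for(self, chain: Chain) -> None:
        if chain == "alpha":
            for t in ("V", "J", "C"):
                if not self.get("alpha", t):
                    raise LocusError(f"alpha chain requires {t} segments")
        else:
            if not self.get("beta", "V") or not self.get("beta", "D"):
                raise LocusError("beta chain requires V and D segments")
            for cas in (1, 2):
                if not self.get("beta", "J", cas) or not self.get("beta", "C", cas):
                    raise LocusError(f"beta cassette {cas} requires J and C segments")


def load_locus_fasta(path) -> GermlineLocus:
    """Read a locus FASTA whose headers are ``name|chain|segtype|cassette``."""
    from Bio import SeqIO

    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 4:
            raise ValueError(f"malformed locus header: {rec.description!r}")
        name, chain, segtype, cassette = parts
        segments.append(
            Segment(
                name=name,
                chain=chain,  # type: ignore[arg-type]
                segtype=segtype,  # type: ignore[arg-type]
                cassette=None if cassette in ("none", "") else int(cassette),
                sequence=str(rec.seq).upper(),
            )
        )
    return GermlineLocus(segments)


def write_locus_fasta(locus: GermlineLocus, path) -> None:
    with open(path, "w") as fh:
        for s in locus.segments:
            cas = "none" if s.cassette is None else str(s.cassette)
            fh.write(f">{s.name}|{s.chain}|{s.segtype}|{cas}\n{s.sequence}\n")


# ---------------------------------------------------------------------------
# productivity
# ---------------------------------------------------------------------------


def _orf_start(sequence: str, v_length: int) -> int | None:
    """Index of the first ATG in the V portion that opens a stop-free ORF
    spanning the whole remaining sequence, or None.

    The frame must end exactly at the final base (span divisible by 3, span
    >= 3); stop codons are disallowed strictly before the final codon.
    """
    n = len(sequence)
    start = sequence.find("ATG")
    while 0 <= start <= v_length - 3:  # codon fully inside the V segment
        span = n - start
        if span >= 3 and span % 3 == 0:
            ok = True
            for j in range(start, n - 3, 3):
                if sequence[j : j + 3] in STOP_CODONS:
                    ok = False
                    break
            if ok:
                return start
        start = sequence.find("ATG", start + 1)
    return None


def is_productive(attempt_sequence: str, v_sequence: str) -> bool:
    """True iff some ATG within the V segment opens a complete ORF.

    The ORF must span from the ATG through the final codon of the constant
    segment with no in-frame stop before that final codon.
    """
    bad = set(attempt_sequence) - _VALID_BASES
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    if not attempt_sequence.startswith(v_sequence):
        raise ValueError("attempt sequence must begin with the chosen V segment")
    return _orf_start(attempt_sequence, len(v_sequence)) is not None


# ---------------------------------------------------------------------------
# rearrangement
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class ChainAttempt:
    """One rearrangement attempt for one chain on one allele."""

    chain: Chain
    allele: int
    attempt_index: int  # 1-based within allele
    segment_names: dict[str, str]
    insertions: list[int]
    sequence: str
    v_length: int
    d_length: int  # 0 for alpha
    j_start: int  # index where J begins in `sequence`
    productive: bool
    orf_start: int | None


def _random_insert(rng: np.random.Generator, lam: float) -> str:
    k = int(rng.poisson(lam))
    if k == 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=k)])


def rearrange_chain(
    chain: Chain,
    locus: GermlineLocus,
    rng: np.random.Generator,
    *,
    attempt_index: int = 1,
    allele: int = 1,
    insertion_lambda: float = DEFAULT_INSERTION_LAMBDA,
) -> ChainAttempt:
    """Simulate a single V(D)J rearrangement attempt.

    Beta: V and D drawn uniformly; J and the matching C come from cassette 1
    on the first attempt of an allele and cassette 2 on the second; Poisson
    insertions at the V-D and VD-J junctions.  Alpha: V and J uniform, one
    C, a single V-J junction.
    """
    locus.validate_for(chain)
    if chain == "beta":
        cassette = 1 if attempt_index == 1 else 2
        v = locus.get("beta", "V")[rng.integers(len(locus.get("beta", "V")))]
        d = locus.get("beta", "D")[rng.integers(len(locus.get("beta", "D")))]
        js = locus.get("beta", "J", cassette)
        cs = locus.get("beta", "C", cassette)
        j = js[rng.integers(len(js))]
        c = cs[rng.integers(len(cs))]
        ins1 = _random_insert(rng, insertion_lambda)
        ins2 = _random_insert(rng, insertion_lambda)
        seq = v.sequence + ins1 + d.sequence + ins2 + j.sequence + c.sequence
        j_start = len(v.sequence) + len(ins1) + len(d.sequence) + len(ins2)
        names = {"V": v.name, "D": d.name, "J": j.name, "C": c.name}
        insertions = [len(ins1), len(ins2)]
        d_len = len(d.sequence)
    else:
        vs = locus.get("alpha", "V")
        js = locus.get("alpha", "J")
        cs = locus.get("alpha", "C")
        v = vs[rng.integers(len(vs))]
        j = js[rng.integers(len(js))]
        c = cs[rng.integers(len(cs))]
        ins1 = _random_insert(rng, insertion_lambda)
        seq = v.sequence + ins1 + j.sequence + c.sequence
        j_start = len(v.sequence) + len(ins1)
        names = {"V": v.name, "J": j.name, "C": c.name}
        insertions = [len(ins1)]
        d_len = 0
    orf = _orf_start(seq, len(v.sequence))
    return ChainAttempt(
        chain=chain,
        allele=allele,
        attempt_index=attempt_index,
        segment_names=names,
        insertions=insertions,
        sequence=seq,
        v_length=len(v.sequence),
        d_length=d_len,
        j_start=j_start,
        productive=orf is not None,
        orf_start=orf,
    )


@dataclass
class Thymocyte:
    """One simulated thymocyte: beta attempts, then alpha attempts if beta
    succeeded (allelic exclusion), and the resulting clonotypes."""

    beta_attempts: list[ChainAttempt] = field(default_factory=list)
    alpha_attempts: list[ChainAttempt] = field(default_factory=list)
    productive_pair: bool = False
    clonotype_beta: str | None = None
    clonotype_alpha: str | None = None

    @property
    def beta_productive(self) -> bool:
        return any(a.productive for a in self.beta_attempts)

    @property
    def alpha_productive(self) -> bool:
        return any(a.productive for a in self.alpha_attempts)

    @property
    def total_inserted_nt(self) -> int:
        return sum(
            sum(a.insertions) for a in self.beta_attempts + self.alpha_attempts
        )


def clonotype(attempt: ChainAttempt, flank_nt: int = 9) -> str:
    """Amino-acid CDR3 clonotype of a productive attempt.

    Translates, in the productive reading frame, the junction window made of
    the last ``flank_nt`` nucleotides of V, the untemplated insertions (plus
    the D segment for beta), and the first ``flank_nt`` nucleotides of J.
    The window is snapped inward to codon boundaries of the productive frame.
    """
    if not attempt.productive or attempt.orf_start is None:
        raise ValueError("clonotype is defined only for productive attempts")
    start = max(attempt.v_length - flank_nt, attempt.orf_start)
    end = min(attempt.j_start + flank_nt, len(attempt.sequence))
    # snap to codon boundaries of the frame anchored at orf_start
    shift = (start - attempt.orf_start) % 3
    if shift:
        start += 3 - shift
    end -= (end - attempt.orf_start) % 3
    if end <= start:
        return ""
    return str(Seq(attempt.sequence[start:end]).translate())


def simulate_thymocyte(
    locus: GermlineLocus,
    rng: np.random.Generator,
    *,
    insertion_lambda: float = DEFAULT_INSERTION_LAMBDA,
    flank_nt: int = 9,
) -> Thymocyte:
    """Simulate one thymocyte's sequential beta-then-alpha rearrangement.

    Beta: cassette-1 then cassette-2 attempts on allele 1; if both fail, the
    same two attempts on allele 2 (up to four attempts).  Alpha (only when a
    beta attempt was productive): one attempt per allele (up to two).
    """
    cell = Thymocyte()
    for allele in (1, 2):
        for attempt_index in (1, 2):
            att = rearrange_chain(
                "beta", locus, rng,
                attempt_index=attempt_index, allele=allele,
                insertion_lambda=insertion_lambda,
            )
            cell.beta_attempts.append(att)
            if att.productive:
                cell.clonotype_beta = clonotype(att, flank_nt)
                break
        if cell.beta_productive:
            break
    if cell.beta_productive:
        for allele in (1, 2):
            att = rearrange_chain(
                "alpha", locus, rng,
                attempt_index=1, allele=allele,
                insertion_lambda=insertion_lambda,
            )
            cell.alpha_attempts.append(att)
            if att.productive:
                cell.clonotype_alpha = clonotype(att, flank_nt)
                break
    cell.productive_pair = cell.beta_productive and cell.alpha_productive
    return cell


@dataclass
class Repertoire:
    """A collection of simulated thymocytes."""

    thymocytes: list[Thymocyte]
    n_attempted: int
    seed: int

    @property
    def productive(self) -> list[Thymocyte]:
        return [t for t in self.thymocytes if t.productive_pair]

    def summary(self) -> dict:
        """Headline fractions and insertion statistics.

        ``frac_beta_valid`` is computed over all simulated thymocytes;
        ``frac_alpha_valid`` over thymocytes that reached alpha rearrangement
        (allelic-exclusion ordering); ``frac_alpha_valid_overall`` over all.
        """
        n = len(self.thymocytes)
        n_beta = sum(t.beta_productive for t in self.thymocytes)
        n_alpha = sum(t.alpha_productive for t in self.thymocytes)
        beta_ins = [
            ins
            for t in self.thymocytes
            for a in t.beta_attempts
            for ins in [sum(a.insertions)]
        ]
        return {
            "n_thymocytes": n,
            "n_attempted": self.n_attempted,
            "frac_beta_valid": n_beta / n if n else float("nan"),
            "frac_alpha_valid": n_alpha / n_beta if n_beta else float("nan"),
            "frac_alpha_valid_overall": n_alpha / n if n else float("nan"),
            "frac_productive_pair": len(self.productive) / n if n else float("nan"),
            "mean_insertions_per_beta_attempt": float(np.mean(beta_ins)) if beta_ins else float("nan"),
        }


def simulate_repertoire(
    locus: GermlineLocus,
    n: int,
    mode: Literal["attempts", "productive"] = "attempts",
    seed: int = 0,
    *,
    insertion_lambda: float = DEFAULT_INSERTION_LAMBDA,
    flank_nt: int = 9,
    max_attempts: int | None = None,
) -> Repertoire:
    """Simulate a repertoire of thymocytes.

    mode="attempts": simulate exactly ``n`` thymocytes.  mode="productive":
    simulate until ``n`` thymocytes carry a productive alpha/beta pair; a
    guard (``max_attempts``, default 1000*n) aborts on loci where
    productivity is impossible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    locus.validate_for("beta")
    locus.validate_for("alpha")
    rng = np.random.default_rng(seed)
    cells: list[Thymocyte] = []
    attempted = 0
    if mode == "attempts":
        for _ in range(n):
            cells.append(
                simulate_thymocyte(locus, rng, insertion_lambda=insertion_lambda, flank_nt=flank_nt)
            )
        attempted = n
    elif mode == "productive":
        cap = max_attempts if max_attempts is not None else 1000 * n
        got = 0
        while got < n:
            if attempted >= cap:
                raise RuntimeError(
                    f"exceeded {cap} attempts with only {got}/{n} productive pairs; "
                    "locus may not admit productive rearrangements"
                )
            cell = simulate_thymocyte(locus, rng, insertion_lambda=insertion_lambda, flank_nt=flank_nt)
            attempted += 1
            cells.append(cell)
            got += cell.productive_pair
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Repertoire(thymocytes=cells, n_attempted=attempted, seed=seed)


# ---------------------------------------------------------------------------
# repertoire statistics
# ---------------------------------------------------------------------------


def shannon_entropy(counts: Iterable[float], base: float = 2.0) -> float:
    """Shannon entropy of a frequency/count vector, in bits by default."""
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    if c.size == 0:
        return 0.0
    f = c / c.sum()
    return float(-(f * (np.log(f) / np.log(base))).sum())


def _productive_attempt(t: Thymocyte, chain: Chain) -> ChainAttempt:
    attempts = t.beta_attempts if chain == "beta" else t.alpha_attempts
    return next(a for a in attempts if a.productive)


def segment_usage(thymocytes: Sequence[Thymocyte], chain: Chain) -> pd.DataFrame:
    """Usage proportions of each segment among productive attempts of one
    chain.  Proportions sum to 1 within each segment class."""
    rows = []
    for t in thymocytes:
        att = _productive_attempt(t, chain)
        for segtype, name in att.segment_names.items():
            rows.append((segtype, name))
    df = pd.DataFrame(rows, columns=["segtype", "segment"])
    out = (
        df.groupby(["segtype", "segment"]).size().rename("count").reset_index()
    )
    out["proportion"] = out.groupby("segtype")["count"].transform(lambda c: c / c.sum())
    out.insert(0, "chain", chain)
    return out


def saturation_stats(
    repertoire: Repertoire,
    sizes: Sequence[int],
    n_seeds: int = 10,
    seed: int = 0,
    entropy_base: float = 2.0,
) -> pd.DataFrame:
    """Subsampling saturation table for repertoire diversity.

    For each subsample size and replicate seed, draws that many productive
    thymocytes without replacement and reports the Shannon entropy (bits by
    default) of alpha and beta CDR3 clonotypes plus segment-usage tables.
    """
    productive = repertoire.productive
    sizes = list(sizes)
    if any(s > len(productive) for s in sizes):
        raise ValueError(
            f"subsample sizes {sizes} exceed the {len(productive)} productive pairs available"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(n_seeds):
            idx = rng.choice(len(productive), size=size, replace=False)
            sub = [productive[i] for i in idx]
            for chain in ("alpha", "beta"):
                clons = pd.Series(
                    [t.clonotype_alpha if chain == "alpha" else t.clonotype_beta for t in sub]
                )
                H = shannon_entropy(clons.value_counts().to_numpy(), base=entropy_base)
                rows.append(
                    {
                        "size": size,
                        "replicate": rep,
                        "chain": chain,
                        "n_clonotypes": clons.nunique(),
                        "entropy": H,
                    }
                )
    return pd.DataFrame(rows)
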