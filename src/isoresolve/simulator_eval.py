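"""Synthetic multigene families, CCS-like reads, and recall/precision scoring.

The generator emulates targeted Iso-Seq sequencing of an ampliconic gene
family: a root gene (an ordered list of exons) spawns near-identical gene
copies by per-base substitution at a mutation rate; isoforms arise by exon
skipping; absolute abundances are drawn from {2^i : i in 1..8} (relative
abundances roughly 0.1%-15% for a 30-isoform family) or set equal; and reads
are sampled from the isoforms with family-specific error rates. Three named
error profiles mirror families spanning the realistic spectrum of transcript
length and CCS accuracy: a short ~914 nt / 6 exon family at 0.5% error, a
~2668 nt / 6 exon family at 2.6%, and a long repetitive ~5904 nt / 28 exon
family at 6.1% (longer transcripts get fewer polymerase passes and therefore
noisier consensus reads).

Per read, the error rate is the profile rate scaled by a lognormal factor
(sigma = 0.5, unit mean) standing in for pass-count variability; a nominal
pass count is drawn around the profile's median passes and recorded on the
read. Errors are substitutions, insertions and deletions in a 1:1:1 mix, and
every emitted base carries Phred quality -10*log10(per-base error rate used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .formats_io import CcsRead

_BASES = np.array(list("ACGT"))

#: name -> (total exon length, number of exons, per-base error rate, median passes)
PROFILES: dict[str, tuple[int, int, float, int]] = {
    "TSPY": (914, 6, 0.005, 18),
    "HSFY": (2668, 6, 0.026, 16),
    "DAZ": (5904, 28, 0.061, 2),
}

ABUNDANCE_VALUES = [2**i for i in range(1, 9)]

_PASS_SIGMA = 0.3     # spread of the nominal pass count around the profile median
_ERR_SIGMA = 0.5      # lognormal spread of the per-read error-rate multiplier


@dataclass
class FamilyConfig:
    """Everything needed to simulate one gene family."""

    root_exons: list[str]
    n_copies: int
    mutation_rate: float
    isoform_patterns: list[tuple[int, ...]]   # exon-inclusion bit vectors
    abundance_values: list[int]
    error_rate: float
    median_passes: int
    seed: int

    def __post_init__(self) -> None:
        n = len(self.root_exons)
        for pat in self.isoform_patterns:
            if len(pat) != n or sum(pat) < 1:
                raise ValueError("every isoform pattern must include >= 1 exon")
        if any(a <= 0 for a in self.abundance_values):
            raise ValueError("abundances must be positive")
        if not 0.0 <= self.mutation_rate <= 0.1:
            raise ValueError("mutation_rate must be in [0, 0.1]")


@dataclass
class TruthSet:
    """Simulated transcripts, their abundances, and per-read origins."""

    transcripts: dict[str, str]               # transcript id -> sequence
    abundance: dict[str, int]                 # transcript id -> absolute abundance
    read_origin: dict[str, str] = field(default_factory=dict)

    @property
    def relative_abundance(self) -> dict[str, float]:
        total = sum(self.abundance.values())
        return {t: a / total for t, a in self.abundance.items()}


def random_root_exons(
    total_length: int, n_exons: int, rng: np.random.Generator, min_exon: int = 30
) -> list[str]:
    """A random root gene split into ``n_exons`` exons of ~equal random sizes."""
    if total_length < n_exons * min_exon:
        raise ValueError("total length too small for the requested exon count")
    cuts = rng.multinomial(total_length - n_exons * min_exon, [1 / n_exons] * n_exons)
    lengths = cuts + min_exon
    seq = "".join(rng.choice(_BASES, size=total_length))
    exons, pos = [], 0
    for ln in lengths:
        exons.append(seq[pos : pos + ln])
        pos += ln
    return exons


def default_isoform_patterns(n_exons: int, n_patterns: int) -> list[tuple[int, ...]]:
    """Deterministic exon-skipping patterns: full inclusion, then single and
    double skips of internal exons (first and last exon always kept, as the
    RT-PCR primers sit in them)."""
    internal = list(range(1, n_exons - 1))
    patterns: list[tuple[int, ...]] = [tuple([1] * n_exons)]
    for i in internal:
        pat = [1] * n_exons
        pat[i] = 0
        patterns.append(tuple(pat))
    for i, j in combinations(internal, 2):
        pat = [1] * n_exons
        pat[i] = pat[j] = 0
        patterns.append(tuple(pat))
    if len(patterns) < n_patterns:
        raise ValueError(f"only {len(patterns)} patterns available for {n_exons} exons")
    return patterns[:n_patterns]


def simulate_copies(
    root_exons: list[str], n_copies: int, mutation_rate: float, seed: int
) -> list[list[str]]:
    """Duplicate gene copies: copy 1 is the root; each later copy derives from
    a uniformly chosen earlier copy with independent per-base substitutions."""
    if not 0.0 <= mutation_rate <= 0.1:
        raise ValueError("mutation_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    copies = [list(root_exons)]
    for _ in range(1, n_copies):
        parent = copies[rng.integers(len(copies))]
        child = [_mutate(exon, mutation_rate, rng) for exon in parent]
        copies.append(child)
    return copies


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_isoforms(
    copies: list[list[str]],
    isoform_patterns: list[tuple[int, ...]],
    abundance_values: list[int],
    seed: int,
) -> TruthSet:
    """Isoforms by exon skipping: one transcript per (copy, pattern) pair.

    Duplicate sequences (copies identical over the included exons) are
    collapsed into a single truth transcript whose abundance is the sum of
    the collapsed ones. Abundances come from a seeded draw of
    ``abundance_values``.
    """
    rng = np.random.default_rng(seed)
    raw: list[str] = []
    for ci, copy in enumerate(copies):
        for pat in isoform_patterns:
            if len(pat) != len(copy):
                raise ValueError("pattern length does not match exon count")
            raw.append("".join(e for e, keep in zip(copy, pat) if keep))
    if len(abundance_values) == len(raw):
        shuffled = list(abundance_values)
        rng.shuffle(shuffled)
    else:
        shuffled = [int(a) for a in rng.choice(abundance_values, size=len(raw))]
    merged: dict[str, int] = {}
    for seq, ab in zip(raw, shuffled):
        merged[seq] = merged.get(seq, 0) + ab
    transcripts = {}
    abundance = {}
    for k, seq in enumerate(sorted(merged, key=lambda s: (-merged[s], s))):
        tid = f"isoform_{k}"
        transcripts[tid] = seq
        abundance[tid] = merged[seq]
    return TruthSet(transcripts, abundance)


def simulate_ccs_reads(
    truth: TruthSet,
    total_reads: int,
    error_profile: str | float,
    seed: int,
    median_passes: int | None = None,
) -> list[CcsRead]:
    """CCS-like reads drawn from the truth set.

    ``error_profile`` is a named profile or an explicit per-base error rate.
    Read origins are recorded in ``truth.read_origin``.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if isinstance(error_profile, str):
        _, _, rate, med_passes = PROFILES[error_profile]
    else:
        rate = float(error_profile)
        med_passes = median_passes if median_passes is not None else 10
    rng = np.random.default_rng(seed)
    tids = sorted(truth.transcripts)
    rel = truth.relative_abundance
    probs = np.array([rel[t] for t in tids])
    origins = rng.choice(len(tids), size=total_reads, p=probs)
    reads: list[CcsRead] = []
    truth.read_origin.clear()
    for i in range(total_reads):
        tid = tids[origins[i]]
        template = truth.transcripts[tid]
        passes = max(1, int(round(rng.lognormal(math.log(med_passes), _PASS_SIGMA))))
        if rate > 0.0:
            mult = rng.lognormal(-_ERR_SIGMA**2 / 2.0, _ERR_SIGMA)
            e = min(rate * mult, 0.5)
            seq, quals = _sequence_with_errors(template, e, rng)
        else:
            seq, quals = template, [93] * len(template)
        rid = f"read_{i:05d}"
        reads.append(CcsRead(rid, seq, quals, num_passes=passes))
        truth.read_origin[rid] = tid
    return reads


def _sequence_with_errors(template: str, e: float, rng: np.random.Generator):
    q = int(min(max(round(-10.0 * math.log10(e)), 1), 93))
    out: list[str] = []
    n = len(template)
    err = rng.random(n) < e
    kinds = rng.integers(3, size=n)        # 0 sub, 1 ins, 2 del
    subs = rng.integers(3, size=n)
    ins = rng.integers(4, size=n)
    for i, base in enumerate(template):
        if not err[i]:
            out.append(base)
            continue
        kind = kinds[i]
        if kind == 0:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[subs[i]])
        elif kind == 1:
            out.append(base)
            out.append("ACGT"[ins[i]])
        # kind == 2: deletion, emit nothing
    if not out:  # pathological all-deleted read; keep one base
        out.append(template[0])
    seq = "".join(out)
    return seq, [q] * len(seq)


def simulate_family(
    profile: str,
    n_copies: int = 5,
    patterns_per_copy: int = 6,
    mutation_rate: float = 0.005,
    equal_abundance: bool = False,
    seed: int = 0,
) -> tuple[FamilyConfig, TruthSet]:
    """Convenience builder for the standard family scenarios.

    The default (5 copies x 6 exon-skipping patterns) yields a 30-isoform
    family; with ``patterns_per_copy=1`` only the full-length transcript of
    each copy is simulated (the mutation-only scenario).
    """
    length, n_exons, rate, med_passes = PROFILES[profile]
    rng = np.random.default_rng(seed)
    root = random_root_exons(length, n_exons, rng)
    patterns = default_isoform_patterns(n_exons, patterns_per_copy)
    cfg = FamilyConfig(
        root_exons=root,
        n_copies=n_copies,
        mutation_rate=mutation_rate,
        isoform_patterns=patterns,
        abundance_values=ABUNDANCE_VALUES,
        error_rate=rate,
        median_passes=med_passes,
        seed=seed,
    )
    copies = simulate_copies(root, n_copies, mutation_rate, seed + 1)
    n_isoforms = n_copies * patterns_per_copy
    if equal_abundance:
        values = [8] * n_isoforms
    else:
        values = [int(v) for v in np.random.default_rng(seed + 2).choice(
            ABUNDANCE_VALUES, size=n_isoforms
        )]
    truth = simulate_isoforms(copies, patterns, values, seed + 3)
    return cfg, truth


def recall_precision(
    predicted: list[str] | dict[str, str], truth: TruthSet, tolerant_ends: int = 0
) -> tuple[float, float]:
    """Exact-sequence recall and precision of predictions against the truth.

    recall = fraction of truth transcripts exactly matched by >= 1 prediction;
    precision = fraction of predictions exactly matching some truth
    transcript. An empty prediction set scores precision 1 and recall 0.
    ``tolerant_ends`` allows up to that many bases of slack at each end.
    """
    preds = list(predicted.values()) if isinstance(predicted, dict) else list(predicted)
    truths = list(truth.transcripts.values())
    if not preds:
        return 0.0, 1.0
    if tolerant_ends == 0:
        pred_set = set(preds)
        truth_set = set(truths)
        recall = sum(1 for t in truths if t in pred_set) / len(truths)
        precision = sum(1 for p in preds if p in truth_set) / len(preds)
        return recall, precision
    matched_t = [any(_ends_match(p, t, tolerant_ends) for p in preds) for t in truths]
    matched_p = [any(_ends_match(p, t, tolerant_ends) for t in truths) for p in preds]
    return sum(matched_t) / len(truths), sum(matched_p) / len(preds)


def _ends_match(a: str, b: str, slack: int) -> bool:
    if abs(len(a) - len(b)) > 2 * slack:
        return False
    if len(a) < len(b):
        a, b = b, a
    for start in range(0, slack + 1):
        if start + len(b) > len(a):
            break
        if a[start : start + len(b)] == b:
            return True
    return a == b
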