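"""Synthetic gut-content shotgun datasets with known ground truth.

Gut-content libraries have a characteristic statistical structure: almost
all reads come from the focal predator's own (nuclear) genome, a small
fraction (of order 0.1-1 %) from its high-copy mitochondrial DNA, and only
tens to hundreds of reads per multi-million-read library from ingested
foreign organisms, whose templates are short because digestion degrades
DNA. This module generates such libraries together with a per-read truth
table so every downstream stage can be tested without sequencing data.

Reference relatives are produced by mutating a common ancestor per lineage
so that realised pairwise divergences straddle the identity thresholds the
filtering stage applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .readqc import Read

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

#: default bounds on the host-mitochondrial read fraction (0.07 %..0.7 %);
#: named predator profiles may sit slightly outside (the richest library in
#: the emulated survey reaches 0.8 %).
DEFAULT_HOST_MT_RANGE = (0.0007, 0.007)


def _enc(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _dec(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _dec(rng.integers(0, 4, size=length).astype(np.uint8))


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    region: Optional[tuple[int, int]] = None,
    force_positions: Optional[Iterable[int]] = None,
) -> str:
    """Substitute a fixed fraction of positions (within ``region`` if given).

    Exactly round(rate * span) distinct positions are substituted to a
    different base; ``force_positions`` are additionally always substituted.
    """
    enc = _enc(seq).copy()
    start, end = region if region is not None else (0, len(seq))
    span = end - start
    n_mut = int(round(rate * span))
    positions = set()
    if n_mut > 0:
        positions.update(
            (start + rng.choice(span, size=n_mut, replace=False)).tolist()
        )
    if force_positions:
        positions.update(int(p) for p in force_positions)
    for p in sorted(positions):
        enc[p] = (enc[p] + 1 + rng.integers(0, 3)) % 4
    return _dec(enc)


def pairwise_divergence(seq_a: str, seq_b: str) -> float:
    """Fraction of differing positions between two equal-length sequences."""
    a, b = _enc(seq_a), _enc(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    return float((a != b).mean())


# ---------------------------------------------------------------------------
# scenario description


@dataclass(frozen=True)
class FragmentModel:
    """Truncated-normal template length model for degraded (ingested) DNA.

    Digested gut DNA is short — the default caps templates at 200 bp with a
    mean of 120 bp — whereas DNA from live host tissue is effectively
    unfragmented at read scale.
    """

    mean: float = 120.0
    sd: float = 40.0
    max_len: int = 200
    min_len: int = 30

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raw = rng.normal(self.mean, self.sd, size=n)
        return np.clip(np.round(raw), self.min_len, self.max_len).astype(np.int64)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base substitution error model with matching Phred strings.

    Base qualities are drawn around q0 = -10*log10(substitution_rate) with a
    small integer jitter; each base's substitution probability is 10^(-q/10),
    so the Phred strings are consistent with the realised error rate.
    Substitution-only by default (MiSeq-like); a rare-indel toggle exists for
    robustness tests.
    """

    substitution_rate: float = 0.002
    quality_jitter: int = 2
    low_quality_fraction: float = 0.0
    low_quality_mean: float = 12.0
    indel_rate: float = 0.0

    @property
    def base_quality(self) -> int:
        return int(round(-10.0 * math.log10(self.substitution_rate)))


@dataclass(frozen=True)
class Member:
    """One community member contributing reads to the library."""

    taxon_id: str
    seq_key: str
    read_fraction: float
    genome_length: int = 16_000
    is_host: bool = False
    fragment: Optional[FragmentModel] = None  # None -> full-length templates


@dataclass
class CommunityScenario:
    """Everything needed to simulate one gut-content library.

    ``members`` must cover all read sources (host nuclear, host
    mitochondrial, foreign) with read fractions summing to 1. ``divergence``
    optionally gives target pairwise divergences (percent) among member
    reference sequences for the star-model genome generator.
    """

    focal_predator: str
    members: list[Member]
    n_reads: int
    read_length: int = 250
    host_mt_fraction: float = 0.002
    error_profile: ErrorProfile = field(default_factory=ErrorProfile)
    divergence: Optional[np.ndarray] = None  # percent, aligned with members
    seed: int = 0
    library_id: str = "lib"

    def validate(self, enforce_host_mt_range: bool = True) -> None:
        total = sum(m.read_fraction for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"member read fractions sum to {total}, not 1")
        if enforce_host_mt_range:
            lo, hi = DEFAULT_HOST_MT_RANGE
            if not (lo <= self.host_mt_fraction <= hi):
                raise ValueError(
                    f"host_mt_fraction {self.host_mt_fraction} outside default "
                    f"range [{lo}, {hi}]"
                )
        for m in self.members:
            if not m.is_host and m.fragment is not None and m.fragment.max_len > 200:
                raise ValueError(
                    f"foreign member {m.taxon_id}: fragment hard max "
                    f"{m.fragment.max_len} > 200 bp"
                )

    @property
    def foreign_members(self) -> list[Member]:
        return [m for m in self.members if not m.is_host]


def build_scenario(
    focal_predator: str,
    foreign_members: list[Member],
    host_mt_fraction: float,
    n_reads: int,
    host_genome_length: int = 500_000,
    mito_length: int = 16_000,
    seed: int = 0,
    **kwargs,
) -> CommunityScenario:
    """Assemble a scenario: host nuclear + host mitochondrial + foreign.

    The host nuclear member absorbs whatever read fraction the foreign
    members and the host mitochondrial fraction leave over.
    """
    foreign_total = sum(m.read_fraction for m in foreign_members)
    host_fraction = 1.0 - foreign_total - host_mt_fraction
    if host_fraction <= 0:
        raise ValueError("foreign fractions + host_mt_fraction exceed 1")
    members = [
        Member(
            taxon_id=focal_predator,
            seq_key=f"{focal_predator}|nuclear",
            read_fraction=host_fraction,
            genome_length=host_genome_length,
            is_host=True,
        ),
        Member(
            taxon_id=focal_predator,
            seq_key=f"{focal_predator}|mito",
            read_fraction=host_mt_fraction,
            genome_length=mito_length,
            is_host=True,
        ),
        *foreign_members,
    ]
    return CommunityScenario(
        focal_predator=focal_predator,
        members=members,
        n_reads=n_reads,
        host_mt_fraction=host_mt_fraction,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# genome generation (star model)


def _solve_tip_rates(target: np.ndarray) -> np.ndarray:
    """Per-tip substitution rates for a star tree.

    Observed divergence between tips i and j under independent substitution
    of exact site counts is r_i + r_j - 4/3 r_i r_j (coincident hits agree
    with probability 1/3). Solved by nonlinear least squares.
    """
    n = target.shape[0]
    if n == 1:
        return np.zeros(1)
    if n == 2:
        d = target[0, 1]
        # symmetric pair: 2r - 4/3 r^2 = d
        disc = 4 - 4 * (4.0 / 3.0) * d
        r = (2 - math.sqrt(disc)) / (2 * 4.0 / 3.0)
        return np.array([r, r])
    iu = np.triu_indices(n, 1)

    def resid(r):
        obs = r[iu[0]] + r[iu[1]] - (4.0 / 3.0) * r[iu[0]] * r[iu[1]]
        return obs - target[iu]

    r0 = np.full(n, target[iu].mean() / 2.0)
    sol = least_squares(resid, r0, bounds=(0.0, 0.74))
    return sol.x


def generate_genomes(
    scenario: CommunityScenario, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], np.ndarray]:
    """Generate member reference sequences at the target pairwise divergences.

    Members that share a divergence matrix are evolved from one common
    ancestor (star model); without a matrix each member gets an independent
    random genome. Returns (genomes keyed by seq_key, realised divergence
    matrix in percent). Deterministic under the scenario seed.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    members = scenario.members
    genomes: dict[str, str] = {}
    n = len(members)
    realized = np.zeros((n, n))
    if scenario.divergence is None:
        for m in members:
            genomes[m.seq_key] = random_sequence(m.genome_length, rng)
        for i in range(n):
            for j in range(i + 1, n):
                if members[i].genome_length == members[j].genome_length:
                    realized[i, j] = realized[j, i] = 100 * pairwise_divergence(
                        genomes[members[i].seq_key], genomes[members[j].seq_key]
                    )
        return genomes, realized

    target = np.asarray(scenario.divergence, dtype=float) / 100.0
    if target.shape != (n, n):
        raise ValueError("divergence matrix shape must match member count")
    if (target < 0).any() or (target > 0.40).any():
        raise ValueError("divergence targets must be within [0, 40] percent")
    lengths = {m.genome_length for m in members}
    if len(lengths) != 1:
        raise ValueError("star-model generation requires equal genome lengths")
    length = lengths.pop()
    ancestor = random_sequence(length, rng)
    rates = _solve_tip_rates(target)
    for m, r in zip(members, rates):
        genomes[m.seq_key] = (
            ancestor if r == 0 else mutate_sequence(ancestor, float(r), rng)
        )
    for i in range(n):
        for j in range(i + 1, n):
            realized[i, j] = realized[j, i] = 100 * pairwise_divergence(
                genomes[members[i].seq_key], genomes[members[j].seq_key]
            )
    return genomes, realized


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth provenance of one simulated read."""

    read_id: str
    taxon_id: str
    seq_id: str
    start: int
    end: int
    is_host: bool


TRUTH_COLUMNS = ["read_id", "taxon_id", "seq_id", "start", "end", "is_host"]


def iter_truth(truth: pd.DataFrame):
    for row in truth.itertuples(index=False):
        yield TruthRecord(
            row.read_id, row.taxon_id, row.seq_id, int(row.start), int(row.end),
            bool(row.is_host),
        )


_CHUNK = 50_000


def _member_reads(
    member: Member,
    genome_enc: np.ndarray,
    count: int,
    scenario: CommunityScenario,
    rng: np.random.Generator,
    id_offset: int,
) -> tuple[list[Read], dict]:
    """Vectorised (chunked) read generation for one member."""
    L = genome_enc.shape[0]
    rl = scenario.read_length
    prof = scenario.error_profile
    reads: list[Read] = []
    ids: list[str] = []
    all_starts = []
    all_tlens = []
    for c0 in range(0, count, _CHUNK):
        c = min(_CHUNK, count - c0)
        if member.fragment is None:
            tlens = np.full(c, min(rl, L), dtype=np.int64)
        else:
            tlens = np.minimum(member.fragment.sample(c, rng), L)
        read_lens = np.minimum(tlens, rl)
        starts = np.floor(rng.random(c) * (L - tlens + 1)).astype(np.int64)
        strands = rng.integers(0, 2, size=c)
        maxlen = int(read_lens.max())

        gather = starts[:, None] + np.arange(maxlen)[None, :]
        np.clip(gather, 0, L - 1, out=gather)
        mat = genome_enc[gather]
        pad_mask = np.arange(maxlen)[None, :] >= read_lens[:, None]

        # reverse-strand reads report the template's other strand
        rev = np.nonzero(strands == 1)[0]
        if rev.size:
            if (read_lens == maxlen).all():
                mat[rev] = _COMP[mat[rev][:, ::-1]]
            else:
                for i in rev:
                    ln = int(read_lens[i])
                    mat[i, :ln] = _COMP[mat[i, :ln][::-1]]

        q = prof.base_quality + rng.integers(
            -prof.quality_jitter, prof.quality_jitter + 1, size=mat.shape
        )
        if prof.low_quality_fraction > 0:
            low = rng.random(c) < prof.low_quality_fraction
            if low.any():
                q[low] = np.clip(
                    np.round(
                        rng.normal(
                            prof.low_quality_mean, 2.0, size=(int(low.sum()), maxlen)
                        )
                    ),
                    2,
                    40,
                ).astype(q.dtype)
        q = np.clip(q, 2, 41)
        p_err = np.power(10.0, q.astype(np.float32) / -10.0)
        err = (rng.random(mat.shape, dtype=np.float32) < p_err) & ~pad_mask
        n_err = int(err.sum())
        if n_err:
            mat[err] = (mat[err] + 1 + rng.integers(0, 3, size=n_err)) % 4
        q = q.astype(np.uint8)

        for i in range(c):
            ln = int(read_lens[i])
            rid = f"{scenario.library_id}:{id_offset + c0 + i:07d}"
            row = mat[i, :ln]
            if prof.indel_rate > 0:
                row = _apply_indels(row.copy(), genome_enc, prof.indel_rate, rng)
                ln = row.shape[0]
                reads.append(Read(rid, _dec(row), q[i, :ln]))
            else:
                reads.append(Read(rid, _dec(row), q[i, :ln].copy()))
            ids.append(rid)
        all_starts.append(starts)
        all_tlens.append(tlens)
    starts = np.concatenate(all_starts) if all_starts else np.empty(0, np.int64)
    tlens = np.concatenate(all_tlens) if all_tlens else np.empty(0, np.int64)
    truth = {
        "read_id": ids,
        "taxon_id": [member.taxon_id] * count,
        "seq_id": [member.seq_key] * count,
        "start": starts,
        "end": starts + tlens,
        "is_host": [member.is_host] * count,
    }
    return reads, truth


def _apply_indels(
    row: np.ndarray, genome_enc: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    n_ind = rng.binomial(row.shape[0], rate)
    for _ in range(int(n_ind)):
        p = int(rng.integers(0, row.shape[0]))
        if rng.random() < 0.5 and row.shape[0] > 1:
            row = np.delete(row, p)
        else:
            row = np.insert(row, p, rng.integers(0, 4))
    return row


def simulate_gut_reads(
    scenario: CommunityScenario,
    genomes: dict[str, str],
    validate: bool = True,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate a library: reads plus a 1:1 truth table.

    Read counts are allocated across members multinomially by read fraction;
    templates shorter than the read length yield shorter reads (degraded
    foreign material). Deterministic — same scenario and seed give
    byte-identical output.
    """
    if validate:
        scenario.validate(enforce_host_mt_range=False)
    if scenario.n_reads == 0:
        return [], pd.DataFrame(columns=TRUTH_COLUMNS)
    rng = np.random.default_rng([scenario.seed, 7_919])
    fractions = np.array([m.read_fraction for m in scenario.members])
    counts = rng.multinomial(scenario.n_reads, fractions)
    all_reads: list[Read] = []
    truth_parts = []
    offset = 0
    for member, count in zip(scenario.members, counts):
        if count == 0:
            continue
        if member.seq_key not in genomes:
            raise KeyError(f"no genome generated for {member.seq_key!r}")
        genome_enc = _enc(genomes[member.seq_key])
        reads, truth = _member_reads(
            member, genome_enc, int(count), scenario, rng, offset
        )
        all_reads.extend(reads)
        truth_parts.append(pd.DataFrame(truth))
        offset += int(count)
    truth_df = (
        pd.concat(truth_parts, ignore_index=True)
        if truth_parts
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    return all_reads, truth_df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scenario (de)serialisation


def scenario_to_yaml(scenario: CommunityScenario) -> str:
    """Serialise a scenario (members, fractions, error model) to YAML."""
    import yaml

    def frag(f: Optional[FragmentModel]):
        if f is None:
            return None
        return {"mean": f.mean, "sd": f.sd, "max_len": f.max_len, "min_len": f.min_len}

    doc = {
        "focal_predator": scenario.focal_predator,
        "n_reads": scenario.n_reads,
        "read_length": scenario.read_length,
        "host_mt_fraction": scenario.host_mt_fraction,
        "seed": scenario.seed,
        "library_id": scenario.library_id,
        "error_profile": {
            "substitution_rate": scenario.error_profile.substitution_rate,
            "quality_jitter": scenario.error_profile.quality_jitter,
            "low_quality_fraction": scenario.error_profile.low_quality_fraction,
            "low_quality_mean": scenario.error_profile.low_quality_mean,
            "indel_rate": scenario.error_profile.indel_rate,
        },
        "members": [
            {
                "taxon_id": m.taxon_id,
                "seq_key": m.seq_key,
                "read_fraction": m.read_fraction,
                "genome_length": m.genome_length,
                "is_host": m.is_host,
                "fragment": frag(m.fragment),
            }
            for m in scenario.members
        ],
    }
    if scenario.divergence is not None:
        doc["divergence"] = np.asarray(scenario.divergence).tolist()
    return yaml.safe_dump(doc, sort_keys=False)


def scenario_from_yaml(text: str) -> CommunityScenario:
    import yaml

    doc = yaml.safe_load(text)
    members = [
        Member(
            taxon_id=m["taxon_id"],
            seq_key=m["seq_key"],
            read_fraction=float(m["read_fraction"]),
            genome_length=int(m.get("genome_length", 16_000)),
            is_host=bool(m.get("is_host", False)),
            fragment=(
                FragmentModel(**m["fragment"]) if m.get("fragment") else None
            ),
        )
        for m in doc["members"]
    ]
    return CommunityScenario(
        focal_predator=doc["focal_predator"],
        members=members,
        n_reads=int(doc["n_reads"]),
        read_length=int(doc.get("read_length", 250)),
        host_mt_fraction=float(doc.get("host_mt_fraction", 0.002)),
        error_profile=ErrorProfile(**doc.get("error_profile", {})),
        divergence=(
            np.asarray(doc["divergence"], dtype=float)
            if "divergence" in doc
            else None
        ),
        seed=int(doc.get("seed", 0)),
        library_id=doc.get("library_id", "lib"),
    )


__all__ = [
    "FragmentModel",
    "ErrorProfile",
    "Member",
    "CommunityScenario",
    "TruthRecord",
    "build_scenario",
    "generate_genomes",
    "simulate_gut_reads",
    "iter_truth",
    "random_sequence",
    "mutate_sequence",
    "pairwise_divergence",
    "write_truth",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "DEFAULT_HOST_MT_RANGE",
]
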