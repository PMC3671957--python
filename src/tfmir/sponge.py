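"""Simulation of miR sequestration ("sponging") by an abundant transcript.

An abundant single-stranded mRNA can soak up complementary microRNAs.  The
simulation scores, for each miR, the most stable intermolecular miR:mRNA
heteroduplex the transcript can form: candidate sites are found by exact
antiparallel complementarity to the miR seed (positions 2-7 by default), each
candidate window is scored with a nearest-neighbor minimum-free-energy
dynamic program over non-crossing intermolecular pairings, and the summed
"energy released" (-dG of the best site per miR, clipped at 0) is compared
against the same score on base-composition-matched shuffled transcripts.  A
real sponge should release more energy than its shuffled doppelgangers.

Only intermolecular pairs are considered: transcript secondary structure and
site accessibility are outside this model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy import EnergyParams

__all__ = [
    "RnaSequence",
    "DuplexHit",
    "SpongeNullResult",
    "CandidateWindow",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "seed_sites",
    "duplex_mfe",
    "best_site",
    "sponge_score",
    "shuffle_composition",
    "dinucleotide_shuffle",
    "run_sponge_null",
]

_ALPHABET = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A,C,G,U}; T is accepted on input and mapped to U."""

    name: str
    bases: str
    role: Literal["transcript", "mir"] = "transcript"

    def __post_init__(self) -> None:
        bases = self.bases.upper().replace("T", "U")
        object.__setattr__(self, "bases", bases)
        if len(bases) < 1:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(bases) - _ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-RNA characters {sorted(bad)}")
        if self.role == "mir" and not 18 <= len(bases) <= 26:
            warnings.warn(
                f"{self.name}: length {len(bases)} outside the typical miR range 18-26",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int, name: str | None = None) -> "RnaSequence":
        return RnaSequence(name or f"{self.name}[{start}:{end}]", self.bases[start:end], self.role)


class CandidateWindow(NamedTuple):
    start: int  # transcript window, 0-based half-open
    end: int
    seed_start: int  # where the seed complement sits on the transcript


@dataclass(frozen=True)
class DuplexHit:
    """One intermolecular duplex: pairs are (transcript index, miR index).

    Pairs are non-crossing under antiparallel reading (transcript index
    ascending while miR index descends); delta_g is the duplex free energy and
    energy_released its negation clipped at zero.
    """

    mir_name: str
    transcript_window: tuple[int, int]
    pairs: tuple[tuple[int, int], ...]
    delta_g: float

    @property
    def energy_released(self) -> float:
        return max(0.0, -self.delta_g)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SpongeNullResult:
    region: str
    true_score: float
    null_scores: tuple[float, ...]
    empirical_p: float
    z_score: float
    n_shuffles: int
    seed: int

    def __post_init__(self) -> None:
        assert len(self.null_scores) == self.n_shuffles


def read_fasta(path: str | Path, role: Literal["transcript", "mir"]) -> list[RnaSequence]:
    return [RnaSequence(rec.id, str(rec.seq), role) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Sequence[RnaSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: RnaSequence, name: str | None = None) -> RnaSequence:
    rc = "".join(_COMPLEMENT[b] for b in reversed(seq.bases))
    return RnaSequence(name or f"{seq.name}_rc", rc, seq.role)


def _can_pair(a: str, b: str, allow_gu: bool) -> bool:
    p = a + b
    if p in {"AU", "UA", "CG", "GC"}:
        return True
    return allow_gu and p in {"GU", "UG"}


def seed_sites(
    transcript: RnaSequence,
    mir: RnaSequence,
    seed_span: tuple[int, int] = (2, 7),
    allow_gu_in_seed: bool = False,
    margin: int = 4,
) -> list[CandidateWindow]:
    """Find candidate target windows by antiparallel seed complementarity.

    ``seed_span`` gives 1-based miR positions (default 2-7).  A match at
    transcript positions [t, t+s) pairs the seed antiparallel (miR position
    ``seed_span[0]`` opposite transcript base t+s-1); the returned window
    extends the match to cover the full miR plus ``margin`` bases of bulge
    slack on both sides, clipped at the transcript ends.
    """
    if len(transcript) <= len(mir):
        raise ValueError("transcript must be longer than the miR")
    lo, hi = seed_span
    if not (1 <= lo < hi <= len(mir)):
        raise ValueError(f"invalid seed span {seed_span} for a {len(mir)}-nt miR")
    s = hi - lo + 1
    L = len(mir)
    tb, mb = transcript.bases, mir.bases
    out: list[CandidateWindow] = []
    for t in range(len(tb) - s + 1):
        # transcript t..t+s-1 pairs miR positions hi..lo (antiparallel)
        ok = all(
            _can_pair(tb[t + k], mb[hi - 1 - k], allow_gu_in_seed) for k in range(s)
        )
        if not ok:
            continue
        # miR 5' end (position 1) extends 3' of the match on the transcript;
        # miR 3' tail (positions hi+1..L) extends 5' of it
        start = max(0, t - (L - hi) - margin)
        end = min(len(tb), t + s + (lo - 1) + margin)
        out.append(CandidateWindow(start, end, t))
    return out


def duplex_mfe(
    window: RnaSequence,
    mir: RnaSequence,
    params: EnergyParams,
    offset: int = 0,
    max_window: int = 40,
) -> DuplexHit:
    """Minimum-free-energy intermolecular duplex between a window and a miR.

    Dynamic program over non-crossing antiparallel pairings: the structure
    energy is ``init_penalty`` plus stacking energies for strand-adjacent
    consecutive pairs and affine bulge / internal-loop penalties for unpaired
    stretches between consecutive pairs (each strand's stretch capped at
    ``max_loop``).  The empty structure (dG = 0) is always admissible.
    Tie-break: lowest energy, then more paired bases, then the pairing whose
    first paired transcript base is 5'-most.
    """
    if len(window) > max_window:
        raise ValueError(f"window length {len(window)} exceeds max {max_window}")
    x, y = window.bases, mir.bases
    n, m = len(x), len(y)
    Lmax = params.max_loop
    can_pair = params.can_pair
    stack = params.stack
    # state: (energy, -n_pairs, first transcript index, parent (i2, j2) | None)
    best: list[list[tuple | None]] = [[None] * m for _ in range(n)]
    for i in range(n):
        xi = x[i]
        for j in range(m - 1, -1, -1):
            if not can_pair(xi, y[j]):
                continue
            state = (params.init_penalty, -1, i, None)
            pair_ij = xi + y[j]
            for i2 in range(max(0, i - 1 - Lmax), i):
                row = best[i2]
                a = i - i2 - 1
                for j2 in range(j + 1, min(m, j + 2 + Lmax)):
                    prev = row[j2]
                    if prev is None:
                        continue
                    b = j2 - j - 1
                    if a == 0 and b == 0:
                        e = stack.get((x[i2] + y[j2], pair_ij))
                        if e is None:
                            continue
                        cost = e
                    elif a == 0 or b == 0:
                        size = a + b
                        if size > Lmax:
                            continue
                        cost = params.bulge_open + params.bulge_extend * (size - 1)
                    else:
                        if a > Lmax or b > Lmax:
                            continue
                        cost = params.internal_open + params.internal_extend * (a + b - 2)
                    cand = (prev[0] + cost, prev[1] - 1, prev[2], (i2, j2))
                    if cand[:3] < state[:3]:
                        state = cand
            best[i][j] = state
    final = None
    final_ij = None
    for i in range(n):
        for j in range(m):
            st = best[i][j]
            if st is not None and (final is None or st[:3] < final[:3]):
                final, final_ij = st, (i, j)
    if final is None or final[:2] >= (0.0, 0):
        # the empty structure wins
        return DuplexHit(mir.name, (offset, offset + n), (), 0.0)
    pairs: list[tuple[int, int]] = []
    ij = final_ij
    st = final
    while ij is not None:
        pairs.append((offset + ij[0], ij[1]))
        ij = st[3]
        if ij is not None:
            st = best[ij[0]][ij[1]]
    pairs.reverse()
    return DuplexHit(mir.name, (offset, offset + n), tuple(pairs), float(final[0]))


def best_site(
    transcript: RnaSequence,
    mir: RnaSequence,
    params: EnergyParams,
    seed_span: tuple[int, int] = (2, 7),
    allow_gu_in_seed: bool = False,
    margin: int = 4,
    max_window: int = 40,
) -> DuplexHit | None:
    """Best (lowest dG) duplex over all seed-match candidate windows.

    Returns ``None`` when the transcript contains no seed match.  Ties go to
    more paired bases, then the 5'-most window.
    """
    candidates = seed_sites(transcript, mir, seed_span, allow_gu_in_seed, margin)
    winner: DuplexHit | None = None
    for w in candidates:
        hit = duplex_mfe(
            transcript.slice(w.start, w.end), mir, params, offset=w.start, max_window=max_window
        )
        if winner is None or (hit.delta_g, -hit.n_pairs, hit.transcript_window[0]) < (
            winner.delta_g,
            -winner.n_pairs,
            winner.transcript_window[0],
        ):
            winner = hit
    return winner


def sponge_score(
    transcript: RnaSequence,
    mirs: Sequence[RnaSequence],
    params: EnergyParams,
    **site_kwargs,
) -> float:
    """Total energy released: sum over miRs of -dG of each best site (>= 0).

    A miR without any seed match contributes 0.
    """
    if not mirs:
        raise ValueError("need at least one miR")
    total = 0.0
    for mir in mirs:
        hit = best_site(transcript, mir, params, **site_kwargs)
        if hit is not None:
            total += hit.energy_released
    return total


def shuffle_composition(
    seq: RnaSequence, seed: int | np.random.Generator = 0
) -> RnaSequence:
    """Uniform random permutation of the bases (exact mononucleotide counts)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.bases.encode(), dtype="S1")
    shuffled = rng.permutation(arr)
    return RnaSequence(f"{seq.name}_shuf", b"".join(shuffled).decode(), seq.role)


def dinucleotide_shuffle(
    seq: RnaSequence, seed: int | np.random.Generator = 0, max_tries: int = 1000
) -> RnaSequence:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Builds the multigraph of adjacent-base transitions and samples a uniform
    Eulerian walk with the same start and end bases as the input: pick a
    random candidate last exit edge per vertex, accept when those edges form
    a tree into the final vertex, then shuffle the remaining edges.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = seq.bases
    if len(s) < 3:
        return RnaSequence(f"{seq.name}_dishuf", s, seq.role)
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(max_tries):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for RNA alphabets
        raise RuntimeError("failed to sample a connected last-edge tree")
    walk_edges: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rest = [rest[k] for k in rng.permutation(len(rest))] if rest else []
        if v in last_edge:
            rest.append(last_edge[v])
        walk_edges[v] = rest
    out = [s[0]]
    cur = s[0]
    used: dict[str, int] = {v: 0 for v in walk_edges}
    for _ in range(len(s) - 1):
        nxt = walk_edges[cur][used[cur]]
        used[cur] += 1
        out.append(nxt)
        cur = nxt
    return RnaSequence(f"{seq.name}_dishuf", "".join(out), seq.role)


def run_sponge_null(
    transcript: RnaSequence,
    utr3: tuple[int, int] | None,
    mirs: Sequence[RnaSequence],
    params: EnergyParams,
    n_shuffles: int = 100,
    seed: int = 0,
    shuffle: Literal["mono", "dinucleotide"] = "mono",
    **site_kwargs,
) -> dict[str, SpongeNullResult]:
    """Compare true sponge scores against composition-matched shuffle nulls.

    Scores the full transcript and, when ``utr3`` (0-based half-open) is
    given, the 3'UTR slice, each against ``n_shuffles`` independently
    shuffled copies of that region.  empirical_p = (1 + #{null >= true}) /
    (1 + n_shuffles); z = (true - null mean) / null sd.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    regions: list[tuple[str, RnaSequence]] = [("full", transcript)]
    if utr3 is not None:
        s, e = utr3
        if not (0 <= s < e <= len(transcript)):
            raise ValueError(f"invalid 3'UTR interval {utr3} for a {len(transcript)}-nt transcript")
        regions.append(("utr3", transcript.slice(s, e, f"{transcript.name}_utr3")))
    shuffler = shuffle_composition if shuffle == "mono" else dinucleotide_shuffle
    out: dict[str, SpongeNullResult] = {}
    for ridx, (region, seq) in enumerate(regions):
        true_score = sponge_score(seq, mirs, params, **site_kwargs)
        rng = np.random.default_rng([seed, ridx])
        null = []
        for _ in range(n_shuffles):
            null.append(sponge_score(shuffler(seq, rng), mirs, params, **site_kwargs))
        null_arr = np.asarray(null)
        p = (1 + int((null_arr >= true_score).sum())) / (1 + n_shuffles)
        sd = float(null_arr.std(ddof=1)) if n_shuffles > 1 else 0.0
        z = (true_score - float(null_arr.mean())) / sd if sd > 0 else 0.0
        out[region] = SpongeNullResult(
            region=region,
            true_score=float(true_score),
            null_scores=tuple(float(v) for v in null),
            empirical_p=float(p),
            z_score=float(z),
            n_shuffles=n_shuffles,
            seed=seed,
        )
    return out
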