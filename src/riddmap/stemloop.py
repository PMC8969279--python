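"""CUGCAG consensus scanning and XBP1-like hairpin folding.

IRE1 cleaves its substrates 3' of the guanine of a CUGCAG consensus
presented in the loop of a stem-loop, the structure first described for the
XBP1 splice sites.  This module scans cleavage windows for the consensus and
asks whether each match can sit in the loop of a hairpin: a stem of at least
``min_stem`` consecutive base pairs (Watson-Crick plus G.U wobble) flanking
a loop of 4-12 unpaired bases that contains the scissile guanine.

Hairpins are ranked by a simple additive energy score — G-C pairs -3, A-U
pairs -2, G.U pairs -1, plus 0.5 per loop nucleotide beyond 4 — chosen to be
deterministic and exactly enumerable rather than a thermodynamic model.  The
minimum-score (most stable) hairpin per consensus match is reported; all
candidate hairpins in the window are enumerated exhaustively.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CleavageSiteCall",
    "Hairpin",
    "scan_consensus",
    "fold_hairpin",
    "call_sites",
    "pair_sites",
    "validate_hairpin",
    "dinucleotide_shuffle",
]

log = logging.getLogger(__name__)

CONSENSUS = "CUGCAG"
CONSENSUS_G_OFFSET = 2  # scissile guanine: CUG|CAG
PAIR_SCORES = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
LOOP_PENALTY_PER_NT = 0.5
LOOP_PENALTY_FREE = 4  # loop nucleotides beyond this many are penalized

_CONSENSUS_RE = re.compile(f"(?={CONSENSUS})")
_RNA_ALPHABET = frozenset("ACGU")


@dataclass
class Hairpin:
    """One stem-loop: 1-based inclusive coordinates on the scanned sequence."""

    loop_start: int
    loop_len: int
    stem_len: int
    energy: float

    @property
    def loop_end(self) -> int:
        return self.loop_start + self.loop_len - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.loop_start - self.stem_len, self.loop_end + self.stem_len

    @property
    def structure(self) -> str:
        """Dot-bracket over the hairpin span."""
        return "(" * self.stem_len + "." * self.loop_len + ")" * self.stem_len


@dataclass
class CleavageSiteCall:
    """A consensus match folded into a hairpin, with the predicted cut site."""

    gene_id: str
    transcript_id: str
    consensus_start: int  # transcript coordinate of the C of CUGCAG
    cleavage_after: int  # coordinate of the guanine 3' of which IRE1 cleaves
    hairpin: Hairpin
    in_window: bool
    group_id: int | None = None

    @property
    def energy(self) -> float:
        return self.hairpin.energy


def _check_rna(seq: str) -> str:
    if "T" in seq:
        log.warning("sequence contains T; converting to U")
        seq = seq.replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def scan_consensus(seq: str) -> list[int]:
    """All 1-based start positions of CUGCAG on the sense strand (overlaps allowed)."""
    seq = _check_rna(seq.upper())
    return [m.start() + 1 for m in _CONSENSUS_RE.finditer(seq)]


def fold_hairpin(
    seq: str,
    match_pos: int,
    window: int = 30,
    min_stem: int = 4,
    loop_range: tuple[int, int] = (4, 12),
) -> Hairpin | None:
    """Best hairpin presenting the consensus guanine of the match in its loop.

    Enumerates every (loop_start, loop_len, stem_len) with a stem of
    consecutive complementary pairs (WC + G.U), loop length within
    *loop_range*, and the scissile guanine unpaired in the loop, all inside
    ``match_pos +/- window``.  Returns the minimum-energy hairpin (ties:
    shortest loop, then 5'-most loop) or None.
    """
    seq = _check_rna(seq.upper())
    L = len(seq)
    g = match_pos + CONSENSUS_G_OFFSET  # 1-based scissile guanine
    win_lo = max(1, match_pos - window)
    win_hi = min(L, match_pos + len(CONSENSUS) - 1 + window)

    best: Hairpin | None = None
    best_key = None
    for loop_len in range(loop_range[0], loop_range[1] + 1):
        for loop_start in range(g - loop_len + 1, g + 1):
            loop_end = loop_start + loop_len - 1
            if loop_start - min_stem < win_lo or loop_end + min_stem > win_hi:
                continue
            # count consecutive complementary pairs closing the loop
            max_s = 0
            while True:
                i = loop_start - (max_s + 1)
                j = loop_end + (max_s + 1)
                if i < win_lo or j > win_hi:
                    break
                if (seq[i - 1], seq[j - 1]) not in PAIR_SCORES:
                    break
                max_s += 1
            if max_s < min_stem:
                continue
            pair_scores = [
                PAIR_SCORES[(seq[loop_start - 1 - t - 1], seq[loop_end + t])]
                for t in range(max_s)
            ]
            loop_pen = LOOP_PENALTY_PER_NT * max(0, loop_len - LOOP_PENALTY_FREE)
            cum = 0.0
            for s in range(1, max_s + 1):
                cum += pair_scores[s - 1]
                if s < min_stem:
                    continue
                energy = cum + loop_pen
                key = (energy, loop_len, loop_start)
                if best_key is None or key < best_key:
                    best_key = key
                    best = Hairpin(loop_start, loop_len, s, energy)
    return best


def validate_hairpin(seq: str, h: Hairpin) -> float:
    """Re-derive the energy of a hairpin from its structure; raises if invalid."""
    seq = _check_rna(seq.upper())
    struct = h.structure
    if struct.count("(") != struct.count(")"):
        raise ValueError("unbalanced dot-bracket")
    energy = 0.0
    for t in range(h.stem_len):
        i = h.loop_start - 1 - t - 1
        j = h.loop_end + t
        pair = (seq[i], seq[j])
        if pair not in PAIR_SCORES:
            raise ValueError(f"non-complementary pair {pair} at stem position {t}")
        energy += PAIR_SCORES[pair]
    energy += LOOP_PENALTY_PER_NT * max(0, h.loop_len - LOOP_PENALTY_FREE)
    return energy


def call_sites(
    windows: list[tuple[str, str, tuple[int, int]]],
    sequences: dict[str, str],
    window: int = 30,
    min_stem: int = 4,
    loop_range: tuple[int, int] = (4, 12),
    permissive: bool = False,
) -> list[CleavageSiteCall]:
    """Scan cleavage windows for consensus-in-hairpin sites.

    Parameters
    ----------
    windows : list of (gene_id, transcript_id, (lo, hi))
        1-based inclusive transcript intervals from the change-point stage.
    sequences : transcript_id -> spliced RNA sequence.
    permissive : when True, consensus matches outside the window are also
        folded and reported with ``in_window=False``.

    Calls are sorted by energy (most stable first).
    """
    calls = []
    for gene_id, tx_id, (lo, hi) in windows:
        seq = sequences.get(tx_id, "")
        if not seq:
            log.warning("empty sequence for transcript %s; skipping", tx_id)
            continue
        for pos in scan_consensus(seq):
            cut = pos + CONSENSUS_G_OFFSET
            inside = lo <= cut <= hi
            if not inside and not permissive:
                continue
            hp = fold_hairpin(seq, pos, window=window, min_stem=min_stem, loop_range=loop_range)
            if hp is None:
                continue
            calls.append(
                CleavageSiteCall(
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    consensus_start=pos,
                    cleavage_after=cut,
                    hairpin=hp,
                    in_window=inside,
                )
            )
    calls.sort(key=lambda c: (c.energy, c.gene_id, c.cleavage_after))
    return calls


def pair_sites(calls: list[CleavageSiteCall], max_gap: int = 200) -> list[list[CleavageSiteCall]]:
    """Group calls on one transcript within *max_gap* nt into multi-site targets.

    Transcripts carrying two nearby consensus-in-hairpin sites (as seen for
    PRDM1- and ATR-like profiles) come out as one group of two.
    """
    by_tx: dict[str, list[CleavageSiteCall]] = {}
    for c in calls:
        by_tx.setdefault(c.transcript_id, []).append(c)
    groups = []
    gid = 0
    for tx in sorted(by_tx):
        cs = sorted(by_tx[tx], key=lambda c: c.cleavage_after)
        current = [cs[0]]
        for c in cs[1:]:
            if c.cleavage_after - current[-1].cleavage_after <= max_gap:
                current.append(c)
            else:
                groups.append(current)
                current = [c]
        groups.append(current)
    for group in groups:
        for c in group:
            c.group_id = gid
        gid += 1
    return groups


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul-Erickson algorithm: treat the sequence as an Eulerian walk on
    the nucleotide digraph, pick a random tree of last-exit edges toward the
    final vertex, shuffle the remaining edge lists, and rebuild the walk.
    """
    seq = _check_rna(seq.upper())
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # choose a last-exit edge per non-final vertex such that every vertex
    # reaches the final one through last-exit edges (rejection sampling)
    while True:
        last_exit = {}
        for v in vertices:
            if v != last:
                last_exit[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen or cur not in edges and cur != last:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_exit[v])
        order = rng.permutation(len(rest))
        rest = [rest[i] for i in order]
        if v != last:
            rest.append(last_exit[v])
        shuffled[v] = rest
    out = [seq[0]]
    cur = seq[0]
    idx = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
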