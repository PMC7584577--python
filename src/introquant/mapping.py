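"""Competitive read mapping against a combined multi-species reference.

Every read is assigned to the best-matching species across the whole genus
panel (all species' loci indexed together), mirroring the combination-
reference strategy used for species identification from shotgun reads.
Seeding uses exact k-mers at every read offset; candidates are scored by
ungapped full-read match count, and the confidence of an assignment is the
*margin*: best score minus the best score achieved by any other species.
The margin is this artifact's mapping-quality proxy — a read that maps
equally well to two species has margin 0 and is discarded by the default
filter, which plays the role of the conventional MQ > 3 uniqueness filter.

Coordinates are 0-based with half-open intervals throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np
import pandas as pd

from .simulate import ReferencePanel, encode_seq

__all__ = [
    "PanelIndex",
    "MappingHit",
    "HitTable",
    "build_index",
    "map_read",
    "map_reads",
    "filter_hits",
    "DEFAULT_K",
    "DEFAULT_MIN_MARGIN",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 21
DEFAULT_MIN_MARGIN = 2


@dataclass(frozen=True)
class MappingHit:
    read_id: str
    species: str
    locus: str
    position: int  # 0-based start within locus
    score: int  # matched bases over the full read
    margin: int  # best minus best-other-species score, >= 0


class PanelIndex:
    """K-mer index over a genus panel (forward strand).

    Internally the panel is concatenated into one code array; postings are
    held as a sorted k-mer-code array with parallel global positions, which
    makes batch lookup a pair of searchsorted calls.  :meth:`postings`
    exposes the conventional k-mer -> [(species, locus, offset), ...] view.
    """

    def __init__(self, panel: ReferencePanel, k: int) -> None:
        if k < 11:
            raise ValueError("k must be >= 11")
        short = [loc for loc, n in panel.lengths.items() if n < k]
        if short:
            raise ValueError(f"loci shorter than k={k}: {short[:5]}")
        self.panel = panel
        self.k = int(k)
        self.species = list(panel.species)

        # concatenate species-major, loci in panel order within each species
        parts = []
        locus_species: list[int] = []
        locus_names: list[str] = []
        locus_lengths: list[int] = []
        for si, sp in enumerate(panel.species):
            for loc in panel.locus_ids:
                parts.append(panel.seqs[(sp, loc)])
                locus_species.append(si)
                locus_names.append(loc)
                locus_lengths.append(panel.seqs[(sp, loc)].size)
        self.ref_codes = np.concatenate(parts)
        self.locus_lengths = np.asarray(locus_lengths, dtype=np.int64)
        self.locus_starts = np.concatenate([[0], np.cumsum(self.locus_lengths)[:-1]]).astype(np.int64)
        self.locus_species = np.asarray(locus_species, dtype=np.int64)
        self.locus_names = np.asarray(locus_names)
        self.total_length = int(self.ref_codes.size)
        # O(1) global-position -> locus lookup
        self._pos2locus = np.repeat(
            np.arange(len(locus_lengths), dtype=np.int32), self.locus_lengths
        )

        kmers, positions = self._all_kmers()
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.sorted_pos = positions[order]

    def _all_kmers(self) -> tuple[np.ndarray, np.ndarray]:
        codes = self.encode_kmers(self.ref_codes[None, :])[0]
        starts = np.arange(self.total_length - self.k + 1, dtype=np.int64)
        # drop windows straddling a locus boundary
        locus_of_start = self._pos2locus[starts]
        end_ok = (
            starts + self.k <= self.locus_starts[locus_of_start] + self.locus_lengths[locus_of_start]
        )
        return codes[end_ok], starts[end_ok]

    def encode_kmers(self, seqs: np.ndarray) -> np.ndarray:
        """Integer codes of every k-mer of every read; seqs is (n, L) uint8.

        Rolling base-4 hash: one vector op per offset instead of a k-wide
        inner product per window.
        """
        k = self.k
        n, L = seqs.shape
        n_off = L - k + 1
        s64 = seqs.astype(np.int64)
        codes = np.empty((n, n_off), dtype=np.int64)
        c = np.zeros(n, dtype=np.int64)
        for j in range(k):
            c = c * 4 + s64[:, j]
        codes[:, 0] = c
        top = np.int64(4) ** (k - 1)
        for i in range(1, n_off):
            c = (c - s64[:, i - 1] * top) * 4 + s64[:, i + k - 1]
            codes[:, i] = c
        return codes

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map global positions to (locus index, species index, offset)."""
        li = self._pos2locus[np.asarray(gpos, dtype=np.int64)].astype(np.int64)
        return li, self.locus_species[li], gpos - self.locus_starts[li]

    def postings(self, kmer: str) -> list[tuple[str, str, int]]:
        """All occurrences of a k-mer as (species, locus, offset) tuples."""
        if len(kmer) != self.k:
            raise ValueError(f"kmer length {len(kmer)} != k={self.k}")
        code = self.encode_kmers(encode_seq(kmer)[None, :])[0, 0]
        lo = np.searchsorted(self.sorted_kmers, code, side="left")
        hi = np.searchsorted(self.sorted_kmers, code, side="right")
        out = []
        for gp in np.sort(self.sorted_pos[lo:hi]):
            li, si, off = self.locate(np.asarray([gp]))
            out.append((self.species[int(si[0])], str(self.locus_names[int(li[0])]), int(off[0])))
        return out

    @property
    def n_postings(self) -> int:
        return int(self.sorted_kmers.size)


class HitTable:
    """Columnar container of mapping hits, tied to the index that made them."""

    def __init__(
        self,
        index: PanelIndex,
        read_index: np.ndarray,
        gstart: np.ndarray,
        score: np.ndarray,
        margin: np.ndarray,
        read_length: int,
        read_ids: Sequence[str] | None = None,
    ) -> None:
        self.index = index
        self.read_index = read_index
        self.gstart = gstart  # global start of the read's placement
        self.score = score
        self.margin = margin
        self.read_length = int(read_length)
        self.read_ids = list(read_ids) if read_ids is not None else None

    def __len__(self) -> int:
        return int(self.read_index.size)

    @property
    def species_idx(self) -> np.ndarray:
        return self.index.locate(self.gstart)[1]

    def to_dataframe(self) -> pd.DataFrame:
        li, si, off = self.index.locate(self.gstart)
        ids = (
            np.asarray(self.read_ids)[self.read_index]
            if self.read_ids is not None
            else self.read_index.astype(str)
        )
        return pd.DataFrame(
            {
                "read_id": ids,
                "species": np.asarray(self.index.species)[si],
                "locus": self.index.locus_names[li],
                "position": off,
                "score": self.score,
                "margin": self.margin,
            }
        )

    def subset(self, rows: np.ndarray) -> "HitTable":
        return HitTable(
            self.index,
            self.read_index[rows],
            self.gstart[rows],
            self.score[rows],
            self.margin[rows],
            self.read_length,
            self.read_ids,
        )


def build_index(panel: ReferencePanel, k: int = DEFAULT_K) -> PanelIndex:
    """Index every k-mer of every species' loci (forward strand)."""
    return PanelIndex(panel, k)


def _revcomp(seqs: np.ndarray) -> np.ndarray:
    return (3 - seqs)[:, ::-1]


def _as_code_matrix(reads, read_length: int | None = None) -> np.ndarray:
    if isinstance(reads, np.ndarray) and reads.dtype == np.uint8:
        return reads
    rows = [encode_seq(r) if isinstance(r, str) else np.asarray(r, dtype=np.uint8) for r in reads]
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError("batch mapping requires equal-length reads")
    return np.vstack(rows)


def map_reads(
    reads,
    index: PanelIndex,
    read_ids: Sequence[str] | None = None,
    both_strands: bool = False,
    _chunk: int = 20_000,
) -> HitTable:
    """Competitively map a batch of equal-length reads.

    Candidate placements come from exact k-mer seeds at every read offset;
    each distinct (read, reference diagonal) candidate is scored by ungapped
    match count over the full read.  The returned table has one row per read
    that produced at least one valid candidate; its ``margin`` is 0 for
    cross-species ties (such reads are dropped by :func:`filter_hits`).
    Output is independent of read order.
    """
    seqs = _as_code_matrix(reads)
    n, L = seqs.shape
    if L < index.k:
        raise ValueError(f"reads ({L} bp) shorter than k={index.k}")

    results = []
    for start in range(0, n, _chunk):
        block = seqs[start : start + _chunk]
        res = _map_block(block, index)
        if both_strands:
            rc = _map_block(_revcomp(block), index)
            res = _better_of(res, rc)
        res = res.copy()
        res[:, 0] += start  # shift read indices to batch coordinates
        results.append(res)
    combined = np.concatenate(results) if results else np.empty((0, 4), dtype=np.int64)
    return HitTable(
        index,
        combined[:, 0],
        combined[:, 1],
        combined[:, 2],
        combined[:, 3],
        read_length=L,
        read_ids=read_ids,
    )


@numba.njit(cache=True)
def _map_kernel(  # pragma: no cover - exercised through map_reads
    seqs,  # (n, L) uint8
    sorted_kmers,  # int64, ascending
    sorted_pos,  # int64, global start of each indexed k-mer
    pos2locus,  # int32, global position -> locus row
    locus_starts,  # int64
    locus_lengths,  # int64
    locus_species,  # int64, locus row -> species index
    ref_codes,  # uint8 concatenated panel
    k,
    n_species,
):
    """Seed-and-score one read at a time.

    For each read: every k-mer (step 1) is looked up in the sorted postings;
    each posting proposes the diagonal the read would start at; diagonals
    whose full-read window stays inside one locus are deduplicated and scored
    by ungapped match count.  Per species the best-scoring diagonal wins
    (ties to the lowest global position = lexicographically lowest
    locus/position); the best species wins overall (cross-species score ties
    give margin 0 and go to the lowest species index).
    """
    n, L = seqs.shape
    n_off = L - k + 1
    n_index = sorted_kmers.size
    top = np.int64(1) << np.int64(2 * (k - 1))
    max_cand = 4096
    cand = np.empty(max_cand, dtype=np.int64)
    sp_best = np.empty(n_species, dtype=np.int64)
    sp_bestg = np.empty(n_species, dtype=np.int64)
    out = np.empty((n, 4), dtype=np.int64)
    n_out = 0
    for r in range(n):
        # rolling base-4 hash over the read
        ncand = 0
        c = np.int64(0)
        for j in range(k):
            c = c * 4 + np.int64(seqs[r, j])
        for i in range(n_off):
            if i > 0:
                c = (c - np.int64(seqs[r, i - 1]) * top) * 4 + np.int64(seqs[r, i + k - 1])
            lo = np.searchsorted(sorted_kmers, c)
            while lo < n_index and sorted_kmers[lo] == c:
                g = sorted_pos[lo] - i
                lo += 1
                if g < 0:
                    continue
                li = pos2locus[g]
                if g + L > locus_starts[li] + locus_lengths[li]:
                    continue
                seen = False
                for t in range(ncand):
                    if cand[t] == g:
                        seen = True
                        break
                if not seen and ncand < max_cand:
                    cand[ncand] = g
                    ncand += 1
        if ncand == 0:
            continue
        # score candidates; track per-species best
        for s in range(n_species):
            sp_best[s] = -1
            sp_bestg[s] = -1
        for t in range(ncand):
            g = cand[t]
            sc = np.int64(0)
            for j in range(L):
                if ref_codes[g + j] == seqs[r, j]:
                    sc += 1
            sp = locus_species[pos2locus[g]]
            if sc > sp_best[sp] or (sc == sp_best[sp] and g < sp_bestg[sp]):
                sp_best[sp] = sc
                sp_bestg[sp] = g
        best_sp = -1
        for s in range(n_species):
            if sp_best[s] >= 0 and (best_sp < 0 or sp_best[s] > sp_best[best_sp]):
                best_sp = s
        second = np.int64(0)
        for s in range(n_species):
            if s != best_sp and sp_best[s] > second:
                second = sp_best[s]
        out[n_out, 0] = r
        out[n_out, 1] = sp_bestg[best_sp]
        out[n_out, 2] = sp_best[best_sp]
        out[n_out, 3] = sp_best[best_sp] - second
        n_out += 1
    return out[:n_out]


def _map_block(seqs: np.ndarray, index: PanelIndex) -> np.ndarray:
    """Map one chunk; returns rows (read_idx, gstart, score, margin)."""
    return _map_kernel(
        np.ascontiguousarray(seqs),
        index.sorted_kmers,
        index.sorted_pos,
        index._pos2locus,
        index.locus_starts,
        index.locus_lengths,
        index.locus_species,
        index.ref_codes,
        index.k,
        len(index.species),
    )


def _better_of(fwd: np.ndarray, rev: np.ndarray) -> np.ndarray:
    """Per read, keep the orientation with the higher best score."""
    merged: dict[int, np.ndarray] = {}
    for row in fwd:
        merged[int(row[0])] = row
    for row in rev:
        cur = merged.get(int(row[0]))
        if cur is None or row[2] > cur[2]:
            merged[int(row[0])] = row
    if not merged:
        return np.empty((0, 4), dtype=np.int64)
    return np.vstack([merged[r] for r in sorted(merged)])


def map_read(read: str, index: PanelIndex, read_id: str = "read", both_strands: bool = False):
    """Map a single read; returns a :class:`MappingHit` or None (unmapped).

    Reads shorter than k are unmapped (reason logged), matching the seeding
    contract rather than raising.
    """
    if len(read) < index.k:
        logger.info("read %s unmapped: shorter than k=%d", read_id, index.k)
        return None
    hits = map_reads([read], index, read_ids=[read_id], both_strands=both_strands)
    if len(hits) == 0:
        return None
    df = hits.to_dataframe().iloc[0]
    return MappingHit(
        read_id=read_id,
        species=str(df["species"]),
        locus=str(df["locus"]),
        position=int(df["position"]),
        score=int(df["score"]),
        margin=int(df["margin"]),
    )


def filter_hits(hits: HitTable, min_margin: int = DEFAULT_MIN_MARGIN) -> HitTable:
    """Keep hits with margin >= min_margin (the uniqueness filter)."""
    if min_margin < 0:
        raise ValueError("min_margin must be >= 0")
    keep = hits.margin >= min_margin
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_hits: removed %d of %d hits (min_margin=%d)", removed, len(hits), min_margin)
    return hits.subset(np.flatnonzero(keep))
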