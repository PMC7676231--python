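"""Read mapping against a gene catalog and gene-count tables.

Implements the quantification chain used for gut shotgun metagenomes:
reads are mapped to a nucleotide gene catalog at a 95% identity threshold,
counted with the two-step "smart shared counting" rule (unique reads first,
shared reads split in proportion to unique counts), downsized to a fixed
sequencing depth by read subsampling, FPKM-normalized, and summarized as
rarefaction-based gene richness with a low/high gene-count split.

The mapper is an exact 31-mer seed + ungapped full-length verifier: a read
maps to a gene when it aligns end-to-end inside the gene at or above the
identity threshold; all genes tied for the best score are kept as shared
hits. This is a desk-scale stand-in for a cohort-scale aligner and is
deliberately simple — no gaps, no clipped alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq

__all__ = [
    "GeneCatalog",
    "ReadSet",
    "ReadMapping",
    "GeneCountTable",
    "GeneQuantConfig",
    "map_reads",
    "smart_shared_count",
    "downsize_counts",
    "compute_gene_richness",
    "fpkm_normalize",
    "classify_gene_count",
    "richness_bimodal_threshold",
]


class GeneCatalog:
    """A nucleotide gene catalog: unique ids, sequences, and lengths."""

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        if any(len(s) < 1 for s in sequences):
            raise ValueError("empty gene sequence")
        self.ids = list(ids)
        self.sequences = list(sequences)
        self.lengths = np.array([len(s) for s in sequences], dtype=np.int64)
        self.index = {g: i for i, g in enumerate(self.ids)}
        self._kmer_index: _KmerIndex | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[self.index[gene_id]]

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=g, description="") for g, s in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "GeneCatalog":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(ids, seqs)

    def kmer_index(self) -> "_KmerIndex":
        if self._kmer_index is None:
            self._kmer_index = _KmerIndex(self)
        return self._kmer_index


class ReadSet:
    """Single-end reads (ids + sequences) with FASTQ round-trip."""

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences differ in length")
        self.ids = list(ids)
        self.sequences = list(sequences)

    def __len__(self) -> int:
        return len(self.ids)

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fastq"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(ids, seqs)


@dataclass
class GeneQuantConfig:
    """Knobs of the quantification chain.

    min_identity is the mapping identity threshold (reads below are
    discarded); downsize_depth is the common sequencing depth reads are
    subsampled to; n_rarefactions the number of independent rarefaction
    draws averaged for gene richness; richness_threshold the low/high
    gene-count split (None = fit a bimodality threshold on the data).
    """

    min_identity: float = 0.95
    downsize_depth: int = 10_000
    n_rarefactions: int = 10
    richness_threshold: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.n_rarefactions < 1:
            raise ValueError("n_rarefactions must be >= 1")


class _KmerIndex:
    """Sorted table of every 31-mer position in the catalog."""

    def __init__(self, catalog: GeneCatalog, k: int = _seq.KMER_K):
        self.k = k
        self.catalog = catalog
        offsets = np.zeros(len(catalog) + 1, dtype=np.int64)
        np.cumsum(catalog.lengths, out=offsets[1:])
        self.flat_offsets = offsets
        self.flat = np.concatenate(
            [_seq.encode(s) for s in catalog.sequences]
        ) if len(catalog) else np.empty(0, dtype=np.uint8)

        codes_parts, gene_parts, pos_parts = [], [], []
        for gi, seq_codes_start in enumerate(offsets[:-1]):
            L = catalog.lengths[gi]
            codes = self.flat[seq_codes_start : seq_codes_start + L]
            vals, valid = _seq.kmer_codes(codes, k)
            if vals.size == 0:
                continue
            keep = np.nonzero(valid)[0]
            codes_parts.append(vals[keep])
            gene_parts.append(np.full(keep.size, gi, dtype=np.int32))
            pos_parts.append(keep.astype(np.int32))
        if codes_parts:
            codes_all = np.concatenate(codes_parts)
            order = np.argsort(codes_all, kind="stable")
            self.codes = codes_all[order]
            self.genes = np.concatenate(gene_parts)[order]
            self.pos = np.concatenate(pos_parts)[order]
        else:
            self.codes = np.empty(0, dtype=np.uint64)
            self.genes = np.empty(0, dtype=np.int32)
            self.pos = np.empty(0, dtype=np.int32)


class ReadMapping:
    """Per-read qualifying hits: read id -> [(gene id, aligned len, identity)].

    Internally array-backed (hit arrays over read/gene indices) so that
    counting and downsizing stay vectorized at cohort depth.
    """

    def __init__(
        self,
        read_ids: Sequence[str],
        gene_ids: Sequence[str],
        hit_read: np.ndarray,
        hit_gene: np.ndarray,
        aligned_len: np.ndarray,
        identity: np.ndarray,
    ):
        if np.any((identity < 0) | (identity > 1)):
            raise ValueError("identity must lie in [0, 1]")
        self.read_ids = list(read_ids)
        self.gene_ids = list(gene_ids)
        order = np.argsort(hit_read, kind="stable")
        self.hit_read = np.asarray(hit_read, dtype=np.int64)[order]
        self.hit_gene = np.asarray(hit_gene, dtype=np.int64)[order]
        self.aligned_len = np.asarray(aligned_len, dtype=np.int64)[order]
        self.identity = np.asarray(identity, dtype=np.float64)[order]

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_mapped(self) -> int:
        return int(np.unique(self.hit_read).size)

    def to_dict(self) -> dict[str, list[tuple[str, int, float]]]:
        out: dict[str, list[tuple[str, int, float]]] = {}
        for r, g, a, i in zip(self.hit_read, self.hit_gene, self.aligned_len, self.identity):
            out.setdefault(self.read_ids[r], []).append((self.gene_ids[g], int(a), float(i)))
        return out

    @classmethod
    def from_hits(
        cls,
        hits: Mapping[str, Sequence[str]],
        gene_ids: Sequence[str],
        read_length: int = 150,
    ) -> "ReadMapping":
        """Build a mapping from {read id: [gene ids]} (identity 1.0), for
        hand-constructed instances."""
        gindex = {g: i for i, g in enumerate(gene_ids)}
        read_ids = list(hits)
        hr, hg = [], []
        for ri, rid in enumerate(read_ids):
            for g in hits[rid]:
                hr.append(ri)
                hg.append(gindex[g])
        n = len(hr)
        return cls(
            read_ids,
            list(gene_ids),
            np.array(hr, dtype=np.int64),
            np.array(hg, dtype=np.int64),
            np.full(n, read_length, dtype=np.int64),
            np.ones(n),
        )


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten [lo, hi) ranges: returns (owner index, flat position)."""
    counts = hi - lo
    total = int(counts.sum())
    owner = np.repeat(np.arange(lo.size), counts)
    flat = np.repeat(lo, counts) + (np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts))
    return owner, flat


def _map_matrix(
    R: np.ndarray,
    read_rows: np.ndarray,
    index: _KmerIndex,
    min_identity: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map rows of read-code matrix R; returns (read_row, gene, matches)."""
    n, L = R.shape
    k = index.k
    if n == 0 or L < k or index.codes.size == 0:
        return (np.empty(0, np.int64),) * 3

    seed_positions = sorted({0, (L - k) // 2, L - k})
    cand_r, cand_g, cand_s = [], [], []
    for p in seed_positions:
        codes = _seq.kmer_codes_at(R, p, k)
        lo = np.searchsorted(index.codes, codes, side="left")
        # run length at lo without a second search (duplicates are rare)
        hi = lo.copy()
        j = 0
        while True:
            pos = lo + j
            ok = (pos < index.codes.size)
            ok[ok] = index.codes[pos[ok]] == codes[ok]
            if not ok.any():
                break
            hi[ok] += 1
            j += 1
        if np.all(lo == hi):
            continue
        owner, flat = _expand_ranges(lo, hi)
        genes = index.genes[flat].astype(np.int64)
        starts = index.pos[flat].astype(np.int64) - p
        # require the read to sit fully inside the gene
        ok = (starts >= 0) & (starts + L <= index.catalog.lengths[genes])
        cand_r.append(owner[ok])
        cand_g.append(genes[ok])
        cand_s.append(starts[ok])
    if not cand_r:
        return (np.empty(0, np.int64),) * 3

    r = np.concatenate(cand_r)
    g = np.concatenate(cand_g)
    s = np.concatenate(cand_s)
    # deduplicate (read, gene, start) triples found by several seeds
    order = np.lexsort((s, g, r))
    r, g, s = r[order], g[order], s[order]
    first = np.ones(r.size, dtype=bool)
    first[1:] = (r[1:] != r[:-1]) | (g[1:] != g[:-1]) | (s[1:] != s[:-1])
    r, g, s = r[first], g[first], s[first]

    seg_idx = (index.flat_offsets[g] + s)[:, None] + np.arange(L)
    mismatches = (index.flat[seg_idx] != R[r]).sum(axis=1)
    matches = (L - mismatches).astype(np.int64)

    # best score per read; all genes tied at the best are kept
    best = np.zeros(n, dtype=np.int64)
    np.maximum.at(best, r, matches)
    keep = (matches == best[r]) & (matches >= min_identity * L)
    r, g, matches = r[keep], g[keep], matches[keep]
    # a gene hit twice at different starts with equal score counts once
    order = np.lexsort((g, r))
    r, g, matches = r[order], g[order], matches[order]
    first = np.ones(r.size, dtype=bool)
    first[1:] = (r[1:] != r[:-1]) | (g[1:] != g[:-1])
    return read_rows[r[first]], g[first], matches[first]


def map_reads(reads: ReadSet, catalog: GeneCatalog, config: GeneQuantConfig) -> ReadMapping:
    """Map reads to the catalog at >= min_identity, keeping all best-score hits.

    Reads are tried on the forward strand; reads without a forward hit get a
    reverse-complement pass. Reads with no qualifying hit stay unmapped.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    index = catalog.kmer_index()

    hit_r: list[np.ndarray] = []
    hit_g: list[np.ndarray] = []
    hit_m: list[np.ndarray] = []
    # group reads by length so each batch is a rectangular matrix
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(reads.sequences):
        by_len.setdefault(len(s), []).append(i)
    for L, rows in by_len.items():
        rows_arr = np.array(rows, dtype=np.int64)
        R = _seq.encode_many([reads.sequences[i] for i in rows])
        r, g, m = _map_matrix(R, rows_arr, index, config.min_identity)
        hit_r.append(r)
        hit_g.append(g)
        hit_m.append(m / L)
        # reverse-complement pass for the unmapped remainder
        un = np.nonzero(~np.isin(rows_arr, r))[0]
        if un.size:
            r2, g2, m2 = _map_matrix(
                _seq.revcomp_codes(R[un]), rows_arr[un], index, config.min_identity
            )
            hit_r.append(r2)
            hit_g.append(g2)
            hit_m.append(m2 / L)

    r = np.concatenate(hit_r) if hit_r else np.empty(0, np.int64)
    g = np.concatenate(hit_g) if hit_g else np.empty(0, np.int64)
    ident = np.concatenate(hit_m) if hit_m else np.empty(0, np.float64)
    alen = np.array([len(reads.sequences[i]) for i in r], dtype=np.int64)
    return ReadMapping(reads.ids, catalog.ids, r, g, alen, ident)


@dataclass
class GeneCountTable:
    """Sample x gene abundance matrix at one processing stage.

    data rows are samples, columns genes. For the raw stage the per-sample
    row sum equals that sample's mapped-read total. assignments retains the
    integer read-to-gene hit arrays so downsizing can subsample *reads*.
    """

    data: pd.DataFrame
    stage: str
    mapped_totals: pd.Series
    assignments: dict[str, tuple[np.ndarray, np.ndarray, int]] | None = None
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "_mapped_total", self.mapped_totals)
        with open(path, "w") as fh:
            fh.write(f"# stage={self.stage}\n")
            df.to_csv(fh, sep="\t", index_label="sample")


def _shared_split(
    hit_read: np.ndarray, hit_gene: np.ndarray, n_reads: int, n_genes: int
) -> np.ndarray:
    """Two-step smart shared counting on hit arrays (read ids < n_reads)."""
    if hit_read.size == 0:
        return np.zeros(n_genes)
    per_read = np.bincount(hit_read, minlength=n_reads)
    unique_hit = per_read[hit_read] == 1
    u = np.bincount(hit_gene[unique_hit], minlength=n_genes).astype(float)
    counts = u.copy()
    sh = ~unique_hit
    if sh.any():
        w_raw = u[hit_gene[sh]]
        denom = np.zeros(n_reads)
        np.add.at(denom, hit_read[sh], w_raw)
        d = denom[hit_read[sh]]
        w = np.where(d > 0, np.divide(w_raw, d, out=np.zeros_like(w_raw), where=d > 0),
                     1.0 / per_read[hit_read[sh]])
        np.add.at(counts, hit_gene[sh], w)
    return counts


def smart_shared_count(
    mappings: Mapping[str, ReadMapping],
    gene_ids: Sequence[str] | None = None,
) -> GeneCountTable:
    """Raw count table from per-sample mappings via smart shared counting.

    Uniquely-mapping reads add 1 to their gene; each shared read is split
    across its candidate genes in proportion to the genes' unique counts
    (equal split when all candidates have zero unique counts). Per sample,
    counts sum to the number of mapped reads.
    """
    if gene_ids is None:
        first = next(iter(mappings.values()))
        gene_ids = first.gene_ids
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)
    rows = {}
    totals = {}
    assignments = {}
    for sample, m in mappings.items():
        if m.gene_ids != gene_ids:
            raise ValueError(f"sample {sample} mapped against a different catalog")
        rows[sample] = _shared_split(m.hit_read, m.hit_gene, m.n_reads, n_genes)
        totals[sample] = m.n_mapped
        assignments[sample] = (m.hit_read.copy(), m.hit_gene.copy(), m.n_reads)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)
    return GeneCountTable(
        data=data,
        stage="raw",
        mapped_totals=pd.Series(totals, dtype=float),
        assignments=assignments,
    )


class _Rarefier:
    """Shared machinery: subsample mapped reads (not hits) without
    replacement and recompute the smart-shared split on the subsample."""

    def __init__(self, hit_read: np.ndarray, hit_gene: np.ndarray, n_reads: int, n_genes: int):
        self.hit_read = hit_read
        self.hit_gene = hit_gene
        self.n_reads = n_reads
        self.n_genes = n_genes
        self.mapped_reads = np.unique(hit_read)
        self.pos = np.searchsorted(self.mapped_reads, hit_read)

    def draw(self, depth: int, rng: np.random.Generator) -> np.ndarray:
        keep = np.zeros(self.mapped_reads.size, dtype=bool)
        keep[rng.permutation(self.mapped_reads.size)[:depth]] = True
        sel = keep[self.pos]
        return _shared_split(
            self.hit_read[sel], self.hit_gene[sel], self.n_reads, self.n_genes
        )


def _require_assignments(table: GeneCountTable) -> None:
    if table.stage != "raw" or table.assignments is None:
        raise ValueError("read-level subsampling requires a raw table with assignments")


def downsize_counts(
    table: GeneCountTable, depth: int, n_reps: int, seed: int
) -> GeneCountTable:
    """Subsample each sample's mapped reads to a common depth.

    Reads are drawn without replacement, the smart-shared split is recomputed
    on the subsample, and the result is averaged over n_reps repetitions.
    Samples with fewer mapped reads than depth are excluded and reported in
    the returned table's `excluded` mapping.
    """
    _require_assignments(table)
    rng = np.random.default_rng(seed)
    n_genes = table.data.shape[1]
    rows, totals, excluded = {}, {}, {}
    for sample in table.samples:
        hit_read, hit_gene, n_reads = table.assignments[sample]
        total = int(table.mapped_totals[sample])
        if total < depth:
            excluded[sample] = f"mapped total {total} < downsize depth {depth}"
            continue
        if total == depth:
            rows[sample] = table.data.loc[sample].to_numpy(copy=True)
        else:
            rarefier = _Rarefier(hit_read, hit_gene, n_reads, n_genes)
            acc = np.zeros(n_genes)
            for _ in range(n_reps):
                acc += rarefier.draw(depth, rng)
            rows[sample] = acc / n_reps
        totals[sample] = float(depth)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=table.data.columns)
    return GeneCountTable(
        data=data,
        stage="downsized",
        mapped_totals=pd.Series(totals, dtype=float),
        excluded=excluded,
    )


@dataclass
class RichnessResult:
    """Per-sample rarefied gene richness plus excluded samples."""

    richness: pd.Series
    excluded: dict[str, str]


def compute_gene_richness(
    table: GeneCountTable, depth: int, n_reps: int, seed: int
) -> RichnessResult:
    """Rarefaction gene richness: mean over n_reps subsamples of the number
    of genes detected (>= 1 read) at the given depth."""
    _require_assignments(table)
    rng = np.random.default_rng(seed)
    n_genes = table.data.shape[1]
    values, excluded = {}, {}
    for sample in table.samples:
        hit_read, hit_gene, n_reads = table.assignments[sample]
        total = int(table.mapped_totals[sample])
        if total < depth:
            excluded[sample] = f"mapped total {total} < rarefaction depth {depth}"
            continue
        if total == depth:
            values[sample] = float((table.data.loc[sample].to_numpy() > 0).sum())
            continue
        rarefier = _Rarefier(hit_read, hit_gene, n_reads, n_genes)
        acc = 0.0
        for _ in range(n_reps):
            acc += float((rarefier.draw(depth, rng) > 0).sum())
        values[sample] = acc / n_reps
    return RichnessResult(pd.Series(values, dtype=float), excluded)


def fpkm_normalize(table: GeneCountTable, catalog: GeneCatalog) -> GeneCountTable:
    """FPKM: count / (gene length in kb) / (sample mapped total in millions)."""
    missing = [g for g in table.data.columns if g not in catalog.index]
    if missing:
        raise KeyError(f"gene(s) missing from catalog: {missing[:5]}")
    lengths_kb = np.array(
        [catalog.lengths[catalog.index[g]] for g in table.data.columns], dtype=float
    ) / 1e3
    totals_m = table.mapped_totals.loc[table.data.index].to_numpy() / 1e6
    if np.any(totals_m <= 0):
        raise ValueError("FPKM undefined for samples with zero mapped reads")
    data = table.data / lengths_kb[None, :] / totals_m[:, None]
    return GeneCountTable(
        data=data,
        stage="fpkm",
        mapped_totals=table.mapped_totals.copy(),
        excluded=dict(table.excluded),
    )


def classify_gene_count(richness, threshold: float):
    """Low/high gene-count split: 'low' iff richness < threshold."""
    if np.any(np.asarray(richness) < 0):
        raise ValueError("negative richness")
    if isinstance(richness, pd.Series):
        return richness.map(lambda r: "low" if r < threshold else "high")
    return "low" if richness < threshold else "high"


def richness_bimodal_threshold(richness: Iterable[float], seed: int = 0) -> float:
    """Valley of a 2-component Gaussian mixture on log10 richness.

    Mirrors defining the low/high gene-count split at the point separating
    the bimodal richness distribution of a reference (healthy) stratum.
    """
    from sklearn.mixture import GaussianMixture

    x = np.log10(np.asarray(list(richness), dtype=float))
    if x.size < 4:
        raise ValueError("too few samples to fit a bimodality threshold")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=5).fit(x[:, None])
    means = np.sort(gm.means_.ravel())
    grid = np.linspace(means[0], means[1], 1001)
    dens = np.exp(gm.score_samples(grid[:, None]))
    return float(10 ** grid[np.argmin(dens)])
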