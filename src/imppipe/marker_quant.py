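"""Histidine-utilization marker quantification.

Two markers of the microbial histidine -> urocanate -> imidazole propionate
route are quantified from shotgun reads:

* urdA (urocanate reductase): reads are counted against short windows built
  around the FAD active site of each reference homolog (the site extended by
  a fixed number of nucleotides on each side). A read counts toward a window
  only when its overlapping segment matches the window exactly — no
  mismatches, no gaps — over strictly more than a minimum overlap, so that
  counted reads genuinely cover the active site. Homologs are classified as
  true or false urocanate reductases by the amino acid at protein position
  373: histidine there abolishes activity, so 'H' means false_urda.
* hutH (histidine ammonia-lyase, KEGG ortholog K01745): the per-sample sum
  of FPKM over catalog genes annotated to the ortholog.

Samples with fewer than a minimum number of window-mapped reads are excluded
(flagged, not erred) and abundances are reported as reads per million.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from .gene_quant import GeneCountTable, ReadSet

__all__ = [
    "UrdaReference",
    "MarkerWindow",
    "MarkerQuantConfig",
    "WindowReadCounts",
    "classify_urda",
    "build_active_site_window",
    "quantify_window_reads",
    "normalize_marker_abundance",
    "quantify_hutH",
    "build_marker_table",
    "write_urda_references",
    "read_urda_references",
]

URDA_CLASSIFYING_POSITION = 373  # 1-based protein residue


def classify_urda(protein: str) -> str:
    """'false_urda' iff residue 373 (1-based) is histidine, else 'true_urda'."""
    if len(protein) < URDA_CLASSIFYING_POSITION:
        raise ValueError(
            f"protein of length {len(protein)} has no residue {URDA_CLASSIFYING_POSITION}"
        )
    return "false_urda" if protein[URDA_CLASSIFYING_POSITION - 1] == "H" else "true_urda"


@dataclass
class UrdaReference:
    """A urocanate-reductase homolog: gene, translation, FAD active site.

    active_site_span is 1-based inclusive nucleotide coordinates on the gene.
    """

    id: str
    sequence: str
    protein: str
    active_site_span: tuple[int, int]

    def __post_init__(self):
        lo, hi = self.active_site_span
        if not (1 <= lo <= hi <= len(self.sequence)):
            raise ValueError(f"active site {self.active_site_span} outside reference {self.id}")
        if len(self.protein) < URDA_CLASSIFYING_POSITION:
            raise ValueError(f"reference {self.id}: protein shorter than residue 373")

    @property
    def residue_373(self) -> str:
        return self.protein[URDA_CLASSIFYING_POSITION - 1]

    @property
    def is_true_urda(self) -> bool:
        return self.residue_373 != "H"

    @property
    def urda_class(self) -> str:
        return classify_urda(self.protein)


@dataclass
class MarkerWindow:
    """Active-site window on a reference: the site extended window_nt each side."""

    reference_id: str
    sequence: str
    span: tuple[int, int]  # 1-based inclusive on the reference
    is_true_urda: bool


@dataclass
class MarkerQuantConfig:
    window_nt: int = 90
    min_reads_per_sample: int = 10
    min_overlap: int = 101  # strictly > 100 bp mapped length
    hutH_ko: str = "K01745"
    seed: int = 0

    def __post_init__(self):
        for name in ("window_nt", "min_reads_per_sample", "min_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def build_active_site_window(ref: UrdaReference, window_nt: int = 90) -> MarkerWindow:
    """Clip [site_start - window_nt, site_end + window_nt] to the reference."""
    lo, hi = ref.active_site_span
    L = len(ref.sequence)
    span = (max(1, lo - window_nt), min(L, hi + window_nt))
    return MarkerWindow(
        reference_id=ref.id,
        sequence=ref.sequence[span[0] - 1 : span[1]],
        span=span,
        is_true_urda=ref.is_true_urda,
    )


def _read_matches_window(read: str, window: str, min_overlap: int) -> bool:
    """Exact-overlap test: some placement of the read against the window has
    an identically matching overlap of >= min_overlap nt."""
    n, w = len(read), len(window)
    if min(n, w) < min_overlap:
        return False
    if n <= w:
        if window.find(read) != -1:
            return True
    else:
        if read.find(window) != -1:
            return True
    # read overhangs the window's left edge: read suffix == window prefix
    for o in range(min_overlap, min(n, w)):
        if read[-o:] == window[:o]:
            return True
    # read overhangs the right edge: read prefix == window suffix
    for o in range(min_overlap, min(n, w)):
        if read[:o] == window[-o:]:
            return True
    return False


def _window_kmer_table(windows: Sequence[MarkerWindow], k: int) -> np.ndarray:
    codes = []
    for w in windows:
        enc = _seq.encode(w.sequence)
        for arr in (enc, _seq.revcomp_codes(enc)):
            vals, valid = _seq.kmer_codes(arr, k)
            codes.append(vals[valid])
    if not codes:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(codes))


@dataclass
class WindowReadCounts:
    """Per-window read tallies for one sample, with the coverage QC flag."""

    per_window: dict[str, int]
    true_reads: int
    false_reads: int
    n_mapped: int
    excluded: bool
    reason: str | None = None


def quantify_window_reads(
    reads: ReadSet, windows: Sequence[MarkerWindow], config: MarkerQuantConfig
) -> WindowReadCounts:
    """Count reads whose overlap with an active-site window matches exactly.

    A read counts toward a window iff the overlapping segment matches with 0
    mismatches and no gaps over strictly more than (min_overlap - 1) nt, on
    either strand. Samples with fewer than min_reads_per_sample total window
    reads are flagged excluded, not erred.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    k = min(_seq.KMER_K, config.min_overlap)
    table = _window_kmer_table(windows, k)

    # k-mer prefilter: a qualifying overlap necessarily contains a window k-mer
    candidates: list[int] = []
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(reads.sequences):
        by_len.setdefault(len(s), []).append(i)
    for L, rows in by_len.items():
        if L < k or table.size == 0:
            continue
        R = _seq.encode_many([reads.sequences[i] for i in rows])
        hit = np.zeros(len(rows), dtype=bool)
        # any overlap of >= min_overlap nt contains a window k-mer starting
        # within (min_overlap - k) positions of the overlap start, so a
        # probe grid of that stride cannot miss a qualifying read
        stride = max(1, config.min_overlap - k)
        probe = sorted({*range(0, L - k + 1, stride), L - k})
        for p in probe:
            codes = _seq.kmer_codes_at(R, p, k)
            idx = np.searchsorted(table, codes)
            ok = idx < table.size
            match = np.zeros_like(hit)
            match[ok] = table[idx[ok]] == codes[ok]
            hit |= match
            if hit.all():
                break
        candidates.extend(np.array(rows)[hit])

    per_window = {w.reference_id: 0 for w in windows}
    true_reads = false_reads = 0
    for i in candidates:
        s = reads.sequences[i]
        rc = _seq.revcomp(s)
        for w in windows:
            if _read_matches_window(s, w.sequence, config.min_overlap) or _read_matches_window(
                rc, w.sequence, config.min_overlap
            ):
                per_window[w.reference_id] += 1
                if w.is_true_urda:
                    true_reads += 1
                else:
                    false_reads += 1
    n_mapped = true_reads + false_reads
    excluded = n_mapped < config.min_reads_per_sample
    return WindowReadCounts(
        per_window=per_window,
        true_reads=true_reads,
        false_reads=false_reads,
        n_mapped=n_mapped,
        excluded=excluded,
        reason=(
            f"{n_mapped} window reads < required {config.min_reads_per_sample}"
            if excluded
            else None
        ),
    )


def normalize_marker_abundance(counts: WindowReadCounts, sample_depth: int) -> dict[str, float]:
    """Reads per million sample reads, split by true/false urdA class."""
    if sample_depth <= 0:
        raise ValueError("sample depth must be positive")
    if counts.excluded:
        raise ValueError("sample excluded by the coverage filter; no abundance defined")
    return {
        "true_urda_rpm": 1e6 * counts.true_reads / sample_depth,
        "false_urda_rpm": 1e6 * counts.false_reads / sample_depth,
    }


def quantify_hutH(
    fpkm: GeneCountTable,
    ko_annotation: Mapping[str, str],
    config: MarkerQuantConfig | None = None,
) -> pd.Series:
    """Per-sample hutH abundance: sum of FPKM over genes annotated to the KO."""
    ko = (config or MarkerQuantConfig()).hutH_ko
    genes = [g for g in fpkm.data.columns if ko_annotation.get(g) == ko]
    if not genes:
        return pd.Series(0.0, index=fpkm.data.index, name="hutH_fpkm")
    return fpkm.data[genes].sum(axis=1).rename("hutH_fpkm")


def build_marker_table(
    counts_by_sample: Mapping[str, WindowReadCounts],
    depths: Mapping[str, int],
    hutH: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample marker abundance table with QC flags."""
    rows = {}
    for sample, counts in counts_by_sample.items():
        if counts.excluded:
            rows[sample] = {
                "true_urda_rpm": np.nan,
                "false_urda_rpm": np.nan,
                "n_window_reads": counts.n_mapped,
                "excluded": True,
                "reason": counts.reason,
            }
        else:
            rpm = normalize_marker_abundance(counts, depths[sample])
            rows[sample] = {
                **rpm,
                "n_window_reads": counts.n_mapped,
                "excluded": False,
                "reason": None,
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if hutH is not None:
        df = df.join(hutH)
    return df


def write_urda_references(refs: Sequence[UrdaReference], fasta_path, sidecar_path) -> None:
    """FASTA of the nucleotide genes + TSV sidecar (span 1-based inclusive)."""
    records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in refs]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "id": [r.id for r in refs],
            "active_site_start": [r.active_site_span[0] for r in refs],
            "active_site_end": [r.active_site_span[1] for r in refs],
            "residue_373": [r.residue_373 for r in refs],
            "protein": [r.protein for r in refs],
        }
    ).to_csv(sidecar_path, sep="\t", index=False)


def read_urda_references(fasta_path, sidecar_path) -> list[UrdaReference]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    side = pd.read_csv(sidecar_path, sep="\t")
    refs = []
    for _, row in side.iterrows():
        refs.append(
            UrdaReference(
                id=row["id"],
                sequence=seqs[row["id"]],
                protein=row["protein"],
                active_site_span=(int(row["active_site_start"]), int(row["active_site_end"])),
            )
        )
    return refs
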