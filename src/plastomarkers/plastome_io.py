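"""Plastid genome records: GenBank I/O, CDS curation, quadripartite
(LSC/IRb/SSC/IRa) structure detection, and assembly summary tables.

Curation mirrors how plastid annotations are prepared for database
submission: coding sequences whose length is not a multiple of three or
that lack a proper start/stop codon are removed; internal stop codons are
masked to 'NNN'; and only genes present in exactly one intact, N-free copy
in every species survive the cross-species intersection.

Coordinates are 0-based half-open everywhere inside the package; GenBank's
1-based closed convention exists only at the file boundary (Biopython
handles the conversion).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "PlastomeRecord",
    "GeneSet",
    "QuadripartiteStructure",
    "read_genbank_plastome",
    "write_genbank_plastome",
    "curate_cds",
    "curate_gene_set",
    "curate_sequence",
    "normalize_gene_name",
    "shared_single_copy_genes",
    "detect_quadripartite",
    "summarize_assemblies",
    "assembly_summary_table",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_START_CODONS = frozenset({"ATG", "GTG"})  # GTG starts occur in plastid genes


@dataclass
class GeneFeature:
    gene_name: str
    type: str  # CDS | tRNA | rRNA
    intervals: list[tuple[int, int]]  # 0-based half-open, ascending
    strand: str  # '+' | '-'


@dataclass
class PlastomeRecord:
    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def spliced(self, feature: GeneFeature) -> str:
        """Strand-resolved spliced sequence: intervals concatenated in
        ascending order, then reverse-complemented as a whole for '-'."""
        parts = "".join(self.sequence[s:e] for s, e in feature.intervals)
        if feature.strand == "-":
            return str(Seq(parts).reverse_complement())
        return parts


@dataclass
class GeneSet:
    """Curated CDS catalogue of one species.

    ``genes`` holds spliced 5'->3' sequences for genes that were retained;
    ``curation_flags`` records the outcome for every annotated gene name.
    """

    species_id: str
    genes: dict[str, str] = field(default_factory=dict)
    curation_flags: dict[str, str] = field(default_factory=dict)


@dataclass
class QuadripartiteStructure:
    """LSC / IRb / SSC / IRa intervals on the circular genome.

    Intervals are (start, end) with start in [0, L) and end = start + length
    (end may exceed L when the interval wraps the origin).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    def lengths(self) -> dict[str, int]:
        return {
            name: iv[1] - iv[0]
            for name, iv in
            (("lsc", self.lsc), ("irb", self.irb), ("ssc", self.ssc), ("ira", self.ira))
        }


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

def _feature_name(feature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return None


def read_genbank_plastome(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a PlastomeRecord.

    CDS/tRNA/rRNA features are kept with multi-interval (join) locations and
    strand; anything unparseable is logged and skipped. A file without a
    GenBank sequence (e.g. plain FASTA) is a format error.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:
        raise ValueError(f"{path} is not a readable GenBank flat file: {exc}") from exc
    if len(record.seq) == 0:
        raise ValueError(f"{path} has no sequence")
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        try:
            name = _feature_name(feat)
            if name is None:
                raise ValueError("feature has no gene/locus_tag/product qualifier")
            strand = "-" if feat.location.strand == -1 else "+"
            intervals = sorted(
                (int(part.start), int(part.end)) for part in feat.location.parts
            )
            features.append(GeneFeature(name, feat.type, intervals, strand))
        except Exception as exc:
            logger.warning("skipping unparseable feature in %s: %s", path, exc)
    return PlastomeRecord(
        id=record.id, sequence=str(record.seq).upper(), features=features
    )


def write_genbank_plastome(record: PlastomeRecord, path: str | Path) -> None:
    """Write a PlastomeRecord back to a GenBank flat file (round-trip safe)."""
    seq_record = SeqRecord(
        Seq(record.sequence), id=record.id, name=record.id[:16],
        description="", annotations={"molecule_type": "DNA"},
    )
    for feat in record.features:
        strand = -1 if feat.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in feat.intervals]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        seq_record.features.append(
            SeqFeature(location, type=feat.type, qualifiers={"gene": [feat.gene_name]})
        )
    SeqIO.write([seq_record], str(path), "genbank")


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

_SUFFIX_RE = re.compile(r"[_-]\d+$")


def normalize_gene_name(name: str) -> str:
    """Case-insensitive gene matching, ignoring numeric locus-tag suffixes."""
    return _SUFFIX_RE.sub("", name.strip()).lower()


def curate_sequence(
    seq: str, start_codons: frozenset[str] = DEFAULT_START_CODONS
) -> tuple[str, str]:
    """Curate one CDS; returns (possibly masked sequence, flag).

    Flags: ``removed_missing_start_stop`` (bad frame, start or terminal
    stop), ``internal_stop_masked`` (internal stops replaced by 'NNN'),
    ``contains_N`` (otherwise intact but carries N), or ``ok``.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0 or len(seq) < 6:
        return seq, "removed_missing_start_stop"
    if seq[:3] not in start_codons or seq[-3:] not in STOP_CODONS:
        return seq, "removed_missing_start_stop"
    codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
    masked = False
    for k in range(1, len(codons) - 1):
        if codons[k] in STOP_CODONS:
            codons[k] = "NNN"
            masked = True
    out = "".join(codons)
    if masked:
        return out, "internal_stop_masked"
    if "N" in out:
        return out, "contains_N"
    return out, "ok"


def curate_cds(
    record: PlastomeRecord, start_codons: frozenset[str] = DEFAULT_START_CODONS
) -> GeneSet:
    """Apply the curation rules to every CDS feature of a record.

    Multi-copy genes (same normalized name annotated more than once) are
    flagged ``multi_copy``; removed genes are dropped from ``genes`` but
    keep their flag.
    """
    by_name: dict[str, list[str]] = {}
    for feat in record.features:
        if feat.type != "CDS":
            continue
        by_name.setdefault(normalize_gene_name(feat.gene_name), []).append(
            record.spliced(feat)
        )
    gs = GeneSet(species_id=record.id)
    for name in sorted(by_name):
        copies = by_name[name]
        if len(copies) > 1:
            gs.curation_flags[name] = "multi_copy"
            gs.genes[name], _ = curate_sequence(copies[0], start_codons)
            continue
        seq, flag = curate_sequence(copies[0], start_codons)
        gs.curation_flags[name] = flag
        if flag != "removed_missing_start_stop":
            gs.genes[name] = seq
    return gs


def curate_gene_set(
    gene_set: GeneSet, start_codons: frozenset[str] = DEFAULT_START_CODONS
) -> GeneSet:
    """Re-curate an existing GeneSet; idempotent (an already-curated set is
    returned unchanged, flags included)."""
    out = GeneSet(species_id=gene_set.species_id,
                  curation_flags=dict(gene_set.curation_flags))
    for name, seq in gene_set.genes.items():
        if gene_set.curation_flags.get(name) == "multi_copy":
            out.genes[name] = seq
            continue
        new_seq, flag = curate_sequence(seq, start_codons)
        if new_seq == seq:
            out.genes[name] = seq  # unchanged: keep the original flag
            continue
        out.curation_flags[name] = flag
        if flag != "removed_missing_start_stop":
            out.genes[name] = new_seq
        else:
            out.genes.pop(name, None)
    return out


def shared_single_copy_genes(gene_sets: list[GeneSet]) -> list[str]:
    """Genes present exactly once, intact and N-free, in *every* species;
    deterministic alphabetical order."""
    if len(gene_sets) < 2:
        raise ValueError("need at least 2 gene sets")
    shared = None
    for gs in gene_sets:
        ok = {name for name, flag in gs.curation_flags.items() if flag == "ok"}
        shared = ok if shared is None else shared & ok
    result = sorted(shared or ())
    if not result:
        logger.warning("no shared single-copy N-free genes across %d species",
                       len(gene_sets))
    return result


# ---------------------------------------------------------------------------
# quadripartite structure
# ---------------------------------------------------------------------------

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

_HASH_MOD = (1 << 61) - 1
_HASH_BASE = 1_000_003


def _prefix_hashes(data: bytes) -> list[int]:
    h = [0] * (len(data) + 1)
    for i, b in enumerate(data):
        h[i + 1] = (h[i] * _HASH_BASE + b) % _HASH_MOD
    return h


def _gram_hashes(prefix: list[int], k: int, n_positions: int) -> np.ndarray:
    p = np.array(prefix, dtype=object)
    bk = pow(_HASH_BASE, k, _HASH_MOD)
    idx = np.arange(n_positions)
    return (p[idx + k] - p[idx] * bk) % _HASH_MOD


def _circular_disjoint(i: int, j: int, k: int, L: int) -> bool:
    return ((j - i) % L) >= k and ((i - j) % L) >= k


def _ir_pairs_at(
    seq2: bytes, rc2: bytes, ph_s: list[int], ph_r: list[int], k: int, L: int
) -> list[tuple[int, int]]:
    """All (i, j) with circular seq[i:i+k] == revcomp(circular seq[j:j+k]),
    disjoint on the circle; verified byte-exactly."""
    hs = _gram_hashes(ph_s, k, L)
    hr = _gram_hashes(ph_r, k, L)
    table: dict[int, list[int]] = {}
    for m, h in enumerate(hr):
        table.setdefault(int(h), []).append(m)
    pairs = []
    for i, h in enumerate(hs):
        for m in table.get(int(h), ()):
            j = (L - m - k) % L
            if not _circular_disjoint(i, j, k, L):
                continue
            if seq2[i: i + k] == rc2[m: m + k]:
                pairs.append((i, j))
    return pairs


def detect_quadripartite(record: PlastomeRecord, min_ir: int = 1000) -> QuadripartiteStructure:
    """Locate the quadripartite structure of a circular plastome.

    Finds the longest pair of disjoint, exactly reverse-complementary
    repeats of length >= ``min_ir`` (binary search over repeat length with
    rolling-hash candidate generation, byte-verified). The longer
    single-copy interval is LSC, the shorter SSC; the repeat copy
    immediately following the LSC is IRb. Among equal-length maximal pairs
    the one minimizing the LSC start is chosen.
    """
    L = record.length
    if L < 4 * min_ir:
        raise ValueError(f"sequence length {L} < 4*min_ir")
    seq = record.sequence.upper().encode("ascii")
    seq2 = seq + seq
    rc = seq.translate(_COMPLEMENT)[::-1]
    rc2 = rc + rc
    ph_s = _prefix_hashes(seq2)
    ph_r = _prefix_hashes(rc2)

    lo, hi = min_ir, L // 2
    best_k = 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if _ir_pairs_at(seq2, rc2, ph_s, ph_r, mid, L):
            best_k = mid
            lo = mid + 1
        else:
            hi = mid - 1
    if best_k < min_ir:
        raise ValueError(f"no inverted repeat of length >= {min_ir} found")

    k = best_k
    candidates = _ir_pairs_at(seq2, rc2, ph_s, ph_r, k, L)

    def layout(i: int, j: int):
        # single-copy stretches between the two repeat copies, going around
        sc1_start, sc1_len = (i + k) % L, (j - i - k) % L
        sc2_start, sc2_len = (j + k) % L, (i - j - k) % L
        if sc1_len >= sc2_len:
            lsc_start, lsc_len, ssc_start, ssc_len = sc1_start, sc1_len, sc2_start, sc2_len
            irb_start, ira_start = j, i  # IRb directly follows the LSC
        else:
            lsc_start, lsc_len, ssc_start, ssc_len = sc2_start, sc2_len, sc1_start, sc1_len
            irb_start, ira_start = i, j
        return lsc_start, lsc_len, ssc_start, ssc_len, irb_start, ira_start

    best = min(candidates, key=lambda ij: layout(*ij)[0])
    lsc_start, lsc_len, ssc_start, ssc_len, irb_start, ira_start = layout(*best)
    return QuadripartiteStructure(
        lsc=(lsc_start, lsc_start + lsc_len),
        irb=(irb_start, irb_start + k),
        ssc=(ssc_start, ssc_start + ssc_len),
        ira=(ira_start, ira_start + k),
        genome_length=L,
    )


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def assembly_summary_table(rows: list[dict]) -> pd.DataFrame:
    """Per-species summary with a two-decimal 'Mean (bp)' row appended.

    Each row dict needs 'species' plus numeric columns (genome_size, lsc,
    irb, ssc, ira, gene counts, ...).
    """
    df = pd.DataFrame(rows).set_index("species")
    mean = df.mean(numeric_only=True).round(2)
    df.loc["Mean (bp)"] = mean
    return df


def summarize_assemblies(
    records: list[PlastomeRecord],
    structures: list[QuadripartiteStructure],
    gene_sets: list[GeneSet],
) -> pd.DataFrame:
    """Assembly summary (genome/LSC/IRb/SSC/IRa lengths and gene counts)."""
    if not (len(records) == len(structures) == len(gene_sets)):
        raise ValueError("records, structures and gene_sets must be parallel lists")
    rows = []
    for rec, st, gs in zip(records, structures, gene_sets):
        lens = st.lengths()
        rows.append(
            {
                "species": rec.id,
                "genome_size": rec.length,
                "lsc": lens["lsc"],
                "irb": lens["irb"],
                "ssc": lens["ssc"],
                "ira": lens["ira"],
                "curated_genes": sum(
                    1 for f in gs.curation_flags.values()
                    if f not in ("removed_missing_start_stop",)
                ),
                "intact_genes": sum(
                    1 for f in gs.curation_flags.values() if f == "ok"
                ),
            }
        )
    return assembly_summary_table(rows)
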