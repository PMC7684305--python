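"""Readers/writers for on-disk formats, run configuration and tag schemes.

All tabular formats are plain TSV with a header line. FASTQ qualities are
fixed to the Phred+33 encoding (modern Illumina); no autodetection is
attempted. Reference FASTA headers carry a ``|``-delimited annotation::

    >record_id|Level1;Level2;Level3;Level4;Genus;species|planktonic

with exactly six semicolon-separated taxonomy levels and a habitat flag
(``planktonic`` or ``benthic``).
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("sedaforam")

DNA_ALPHABET = "ACGT"
TAG_LENGTH = 8

#: length window (bp) of the 37f hypervariable metabarcode region
DEFAULT_LENGTH_WINDOW = (68, 196)

HABITATS = ("planktonic", "benthic")
ZONES = ("LC", "transition", "NAC")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class PairingError(ValueError):
    """Two FASTQ files that should be positionally paired are not."""


class DesignError(ValueError):
    """A simulation design is internally inconsistent or degenerate."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# tag scheme
# ---------------------------------------------------------------------------


@dataclass
class TagScheme:
    """Per-sample 8-nt forward/reverse tag combinations.

    Tag pairs are arranged as a Latin-square style combination matrix: each
    sample owns a unique (forward tag, reverse tag) cell, so the pair
    identifies the sample after sequencing.
    """

    samples: list[str]
    fwd_tags: list[str]
    rev_tags: list[str]
    assignment: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for tag in list(self.fwd_tags) + list(self.rev_tags):
            if len(tag) != TAG_LENGTH or any(b not in DNA_ALPHABET for b in tag):
                raise FormatError(f"invalid 8-nt tag: {tag!r}")
        if set(self.assignment) != set(self.samples):
            raise FormatError("tag assignment does not cover the sample list")
        pairs = list(self.assignment.values())
        if len(set(pairs)) != len(pairs):
            raise FormatError("two samples share the same (fwd, rev) tag pair")
        for i, j in pairs:
            if not (0 <= i < len(self.fwd_tags) and 0 <= j < len(self.rev_tags)):
                raise FormatError("tag index out of range")

    def tags_for(self, sample: str) -> tuple[str, str]:
        i, j = self.assignment[sample]
        return self.fwd_tags[i], self.rev_tags[j]

    @classmethod
    def latin_square(
        cls,
        samples: Sequence[str],
        seed: int = 0,
        min_distance: int = 6,
        max_tries: int = 20000,
    ) -> "TagScheme":
        """Build a scheme whose tag sets have pairwise Hamming distance
        ``>= min_distance`` within each set.

        With the default of 6, any read carrying at most 2 tag mismatches
        decodes uniquely and a read with 3 mismatches can never be closer
        than 3 to a wrong sample, so it stays unassigned rather than being
        misassigned.
        """
        rng = np.random.default_rng(seed)
        n = len(samples)
        if n == 0:
            raise DesignError("no samples to tag")
        n_fwd = int(np.ceil(np.sqrt(n)))
        n_rev = int(np.ceil(n / n_fwd))

        def make_set(k: int) -> list[str]:
            tags: list[str] = []
            for _ in range(max_tries):
                cand = "".join(rng.choice(list(DNA_ALPHABET), size=TAG_LENGTH))
                if all(
                    sum(a != b for a, b in zip(cand, t)) >= min_distance for t in tags
                ):
                    tags.append(cand)
                    if len(tags) == k:
                        return tags
            raise DesignError(
                f"could not build {k} tags at pairwise distance >= {min_distance}"
            )

        fwd, rev = make_set(n_fwd), make_set(n_rev)
        assignment = {
            s: (idx // n_rev, idx % n_rev) for idx, s in enumerate(samples)
        }
        return cls(list(samples), fwd, rev, assignment)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tfwd_tag\trev_tag\n")
            for s in self.samples:
                f, r = self.tags_for(s)
                fh.write(f"{s}\t{f}\t{r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns) != ["sample", "fwd_tag", "rev_tag"]:
            raise FormatError(f"unexpected tag-scheme columns: {list(df.columns)}")
        fwd = sorted(set(df["fwd_tag"]))
        rev = sorted(set(df["rev_tag"]))
        assignment = {
            row["sample"]: (fwd.index(row["fwd_tag"]), rev.index(row["rev_tag"]))
            for _, row in df.iterrows()
        }
        return cls(list(df["sample"]), fwd, rev, assignment)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every threshold of the processing chain, serializable to YAML.

    The printed defaults are the study conditions: read pairs are kept when
    each mate's mean Phred score is strictly above 30, merged with a minimum
    exact overlap of 12 bases, demultiplexed allowing at most 2 mismatches
    over both tagged-primer constructs, assigned when best identity is
    strictly above 0.80, classified planktonic at >= 0.95 identity, and OTUs
    are retained when present in strictly more than 3 samples.
    """

    mean_phred_min: float = 30.0
    min_overlap: int = 12
    tag_mismatch_max: int = 2
    identity_floor: float = 0.80
    otu_assign_identity: float = 0.95
    min_samples_per_otu: int = 3
    chimera_parent_ratio: float = 2.0
    chimera_identity: float = 0.99
    chimera_max_parents: int = 20
    precluster_signature_length: int = 30
    otu_distance_threshold: float = 0.03
    otu_threshold_overrides: dict[str, float] = field(default_factory=dict)
    merge_variants: bool = False
    nw_match: int = 1
    nw_mismatch: int = -1
    nw_gap: int = -2
    css_percentile: float = 0.5
    css_scale: float = 1000.0
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.identity_floor < self.otu_assign_identity <= 1):
            raise FormatError(
                "need 0 < identity_floor < otu_assign_identity <= 1, got "
                f"{self.identity_floor} / {self.otu_assign_identity}"
            )
        if self.min_overlap < 1:
            raise FormatError("min_overlap must be >= 1")
        if self.tag_mismatch_max < 0:
            raise FormatError("tag_mismatch_max must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


@dataclass
class ReadPair:
    id: str
    seq_fwd: str
    qual_fwd: list[int]
    seq_rev: str
    qual_rev: list[int]


def _decode_phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def read_fastq_pairs(path_fwd: str | Path, path_rev: str | Path) -> Iterator[ReadPair]:
    """Stream positionally paired reads from two FASTQ files.

    Qualities are decoded as Phred+33 integers. Raises :class:`PairingError`
    when the two files hold different record counts and :class:`FormatError`
    (with the record index) on a malformed record.
    """
    _SENTINEL = object()
    with _open_text(path_fwd) as ff, _open_text(path_rev) as fr:
        it_f = FastqGeneralIterator(ff)
        it_r = FastqGeneralIterator(fr)
        idx = 0
        while True:
            try:
                rec_f = next(it_f, _SENTINEL)
                rec_r = next(it_r, _SENTINEL)
            except ValueError as exc:
                raise FormatError(f"malformed FASTQ record at index {idx}: {exc}")
            if rec_f is _SENTINEL and rec_r is _SENTINEL:
                return
            if rec_f is _SENTINEL or rec_r is _SENTINEL:
                raise PairingError(
                    f"FASTQ files diverge at record {idx}: one file is exhausted"
                )
            title_f, seq_f, qual_f = rec_f
            _, seq_r, qual_r = rec_r
            yield ReadPair(
                title_f.split()[0],
                seq_f.upper(),
                _decode_phred(qual_f),
                seq_r.upper(),
                _decode_phred(qual_r),
            )
            idx += 1


def write_fastq_pair(
    records: Sequence[tuple[str, str, str]],
    path_fwd: str | Path,
    path_rev: str | Path,
    quality_char: str = "F",
) -> None:
    """Write (id, fwd_seq, rev_seq) triples as a FASTQ pair with constant quality."""
    with _open_text(path_fwd, "wt") as ff, _open_text(path_rev, "wt") as fr:
        for rid, sf, sr in records:
            ff.write(f"@{rid}\n{sf}\n+\n{quality_char * len(sf)}\n")
            fr.write(f"@{rid}\n{sr}\n+\n{quality_char * len(sr)}\n")


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------


@dataclass
class RefRecord:
    id: str
    taxonomy: tuple[str, ...]
    habitat: str
    sequence: str


@dataclass
class ReferenceDB:
    """Taxonomy-annotated barcode sequences trimmed to the 37f region."""

    records: list[RefRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def planktonic_only(self) -> "ReferenceDB":
        return ReferenceDB([r for r in self.records if r.habitat == "planktonic"])

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id}|{';'.join(r.taxonomy)}|{r.habitat}\n{r.sequence}\n")


def read_reference_fasta(
    path: str | Path,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> ReferenceDB:
    """Parse an annotated reference FASTA into a :class:`ReferenceDB`.

    Headers must carry a 6-level ``;``-separated taxonomy path and a habitat
    flag between ``|`` separators; sequences outside ``length_window`` are
    rejected.
    """
    records: list[RefRecord] = []
    seen: set[str] = set()
    lo, hi = length_window
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split("|")
        if len(parts) != 3:
            raise FormatError(f"reference header needs id|taxonomy|habitat: {header!r}")
        rid, taxpath, habitat = parts
        levels = tuple(taxpath.split(";"))
        if len(levels) != 6:
            raise FormatError(f"taxonomy of {rid!r} has {len(levels)} levels, need 6")
        if habitat not in HABITATS:
            raise FormatError(f"unknown habitat {habitat!r} for {rid!r}")
        if rid in seen:
            raise FormatError(f"duplicate reference id {rid!r}")
        seen.add(rid)
        seq = "".join(chunks).upper()
        if not (lo <= len(seq) <= hi):
            raise FormatError(
                f"sequence of {rid!r} has length {len(seq)}, outside {length_window}"
            )
        records.append(RefRecord(rid, levels, habitat, seq))

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        flush()
    return ReferenceDB(records)


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------


def write_otu_table(
    counts: pd.DataFrame,
    path: str | Path,
    taxonomy: pd.Series | None = None,
    habitat: pd.Series | None = None,
) -> None:
    """Write an OTU x sample integer count table as TSV.

    ``counts`` has OTU ids on the index and sample ids as columns; taxonomy
    and habitat annotations, when given, are appended as trailing columns.
    """
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise FormatError("OTU table requires unique OTU and sample identifiers")
    out = counts.copy()
    out.index.name = "otu_id"
    if taxonomy is not None:
        out["taxonomy"] = taxonomy.reindex(counts.index)
    if habitat is not None:
        out["habitat"] = habitat.reindex(counts.index)
    out.to_csv(path, sep="\t")


def read_otu_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an OTU table written by :func:`write_otu_table`.

    Returns ``(counts, annotations)`` where counts are integer OTU x sample
    values and annotations holds any trailing non-count columns.
    """
    df = pd.read_csv(path, sep="\t", index_col="otu_id")
    ann_cols = [c for c in ("taxonomy", "habitat") if c in df.columns]
    ann = df[ann_cols]
    counts = df.drop(columns=ann_cols)
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any() or (vals != vals.round()).any():
            raise FormatError(f"non-integer count in column {col!r}")
        counts[col] = vals.astype(int)
    return counts, ann


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample, site, depth_cm_top, depth_cm_bottom, zone)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "site": str, "zone": str})
    required = {"sample", "site", "depth_cm_top", "depth_cm_bottom", "zone"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    bad = set(df["zone"]) - set(ZONES)
    if bad:
        raise FormatError(f"unknown hydrographic zones: {sorted(bad)}")
    return df.set_index("sample")


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample")
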