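"""Amplicon-processing chain for foraminiferal 37f metabarcodes.

Stage order: quality filter -> merge -> demultiplex -> chimera removal ->
dereplicate -> taxonomic assignment -> precluster -> average-linkage OTU
clustering -> planktonic/benthic classification -> occupancy filter ->
(optional) intragenomic-variant merging.

Every stage logs input/output record counts so reads can be accounted for
end to end: assigned + unassigned + dropped = raw.

Conventions adopted where the method leaves room:

* identity = matching columns / alignment columns, gap columns counted in
  the denominator;
* among co-optimal global alignments the one maximizing matches and then
  minimizing alignment columns is used (deterministic);
* "above" thresholds (mean Phred 30, 80% identity floor) are strict,
  the 95% classification threshold is inclusive;
* ties are broken lexicographically on sequence, then identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import PipelineConfig, ReadPair, ReferenceDB, TagScheme, read_fastq_pairs, revcomp

logger = logging.getLogger("sedaforam.pipeline")

__all__ = [
    "ISU",
    "OTU",
    "PipelineResult",
    "quality_filter",
    "merge_pair",
    "demultiplex",
    "dereplicate",
    "detect_chimeras",
    "nw_align",
    "nw_identity",
    "nw_match_profile",
    "assign_isu",
    "precluster",
    "cluster_otus",
    "classify_otu",
    "filter_otus",
    "merge_variant_otus",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ISU:
    """Individual Sequence Unit: one dereplicated sequence with per-sample counts."""

    sequence: str
    counts: dict[str, int]
    taxonomy: tuple[str, ...] | None = None
    best_identity: float = 0.0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class OTU:
    """Cluster of ISUs with a representative sequence and summed abundances."""

    members: list[ISU]
    representative: str
    taxonomy: tuple[str, ...] | None
    habitat: str | None = None
    planktonic_taxon: tuple[str, ...] | None = None

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            for s, c in m.counts.items():
                out[s] = out.get(s, 0) + c
        return out

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# read-level stages
# ---------------------------------------------------------------------------


def quality_filter(pair: ReadPair, mean_phred_min: float = 30.0) -> bool:
    """Keep a read pair iff the mean Phred score of *each* mate is strictly
    above the threshold."""
    if not pair.qual_fwd or not pair.qual_rev:
        return False
    return (
        sum(pair.qual_fwd) / len(pair.qual_fwd) > mean_phred_min
        and sum(pair.qual_rev) / len(pair.qual_rev) > mean_phred_min
    )


def merge_pair(fwd: str, rev: str, min_overlap: int = 12) -> str | None:
    """Assemble a pair by the largest exact suffix(fwd)/prefix(revcomp(rev))
    overlap of length >= ``min_overlap``; no mismatch is tolerated.

    Returns the merged sequence or ``None`` when no qualifying overlap exists.
    """
    if not fwd or not rev:
        raise ValueError("mates must be non-empty")
    rc = revcomp(rev)
    for k in range(min(len(fwd), len(rc)), min_overlap - 1, -1):
        if fwd[-k:] == rc[:k]:
            return fwd + rc[k:]
    return None


def _hamming(a: str, b: str, cutoff: int) -> int:
    """Hamming distance with early abort once ``cutoff`` is exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cutoff:
                return d
    return d


class Demultiplexer:
    """Assign merged reads to samples by their inline tagged-primer constructs.

    The 5' block of a merged read is compared (Hamming) to each sample's
    ``fwd_tag + fwd_primer`` construct and the 3' block to the reverse
    complement of ``rev_tag + rev_primer``; the two distances are summed.
    A read goes to the unique sample at minimal summed distance
    <= ``tag_mismatch_max``; equal minimal distance between two samples is an
    ambiguity and the read stays unassigned.
    """

    def __init__(
        self,
        scheme: TagScheme,
        fwd_primer: str,
        rev_primer: str,
        tag_mismatch_max: int = 2,
    ) -> None:
        self.scheme = scheme
        self.max_mm = tag_mismatch_max
        self.head_len = len(scheme.fwd_tags[0]) + len(fwd_primer)
        self.tail_len = len(scheme.rev_tags[0]) + len(rev_primer)
        self.constructs: list[tuple[str, str, str]] = []
        exact: dict[tuple[str, str], str] = {}
        for s in scheme.samples:
            ft, rt = scheme.tags_for(s)
            head = ft + fwd_primer
            tail = revcomp(rt + rev_primer)
            self.constructs.append((s, head, tail))
            exact[(head, tail)] = s
        self._exact = exact

    def __call__(self, merged: str) -> tuple[str | None, str | None]:
        """Return ``(sample, insert)`` or ``(None, None)`` for unassigned."""
        if len(merged) < self.head_len + self.tail_len:
            return None, None
        head = merged[: self.head_len]
        tail = merged[-self.tail_len :]
        hit = self._exact.get((head, tail))
        if hit is not None:
            return hit, merged[self.head_len : -self.tail_len]
        best: str | None = None
        best_d = self.max_mm + 1
        ambiguous = False
        for s, h, t in self.constructs:
            d = _hamming(head, h, best_d)
            if d <= best_d:
                d += _hamming(tail, t, best_d - d)
            if d < best_d:
                best, best_d, ambiguous = s, d, False
            elif d == best_d and best is not None:
                ambiguous = True
        if best is None or ambiguous or best_d > self.max_mm:
            return None, None
        return best, merged[self.head_len : -self.tail_len]


def demultiplex(
    merged: str,
    scheme: TagScheme,
    fwd_primer: str,
    rev_primer: str,
    tag_mismatch_max: int = 2,
) -> tuple[str | None, str | None]:
    """One-shot convenience wrapper around :class:`Demultiplexer`."""
    return Demultiplexer(scheme, fwd_primer, rev_primer, tag_mismatch_max)(merged)


def dereplicate(inserts: Iterable[tuple[str, str]]) -> list[ISU]:
    """Collapse identical full-length inserts into ISUs with per-sample counts.

    ``inserts`` yields ``(sample, sequence)``; the summed ISU counts equal the
    number of input records. ISUs are returned sorted by descending total
    abundance, ties broken lexicographically on sequence.
    """
    table: dict[str, dict[str, int]] = {}
    for sample, seq in inserts:
        per = table.setdefault(seq, {})
        per[sample] = per.get(sample, 0) + 1
    isus = [ISU(seq, counts) for seq, counts in table.items()]
    isus.sort(key=lambda u: (-u.total, u.sequence))
    return isus


# ---------------------------------------------------------------------------
# Needleman-Wunsch alignment
# ---------------------------------------------------------------------------


def nw_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[int, int, int]:
    """Global alignment of two sequences (linear gap penalty, end gaps charged).

    Returns ``(score, matches, alignment_columns)`` of the optimal alignment;
    among co-optimal alignments the one with the most matches, then the
    fewest columns, is selected. The three additive quantities are folded
    into one integer key so the dynamic program optimizes them
    lexicographically in a single pass.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    L = n + m
    # encoded value = score*KS + matches*KM - columns; KM exceeds the column
    # range and KS exceeds the matches*KM - columns range, so integer order
    # equals lexicographic order on (score, matches, -columns).
    KM = 2 * L + 2
    KS = KM * (L + 2)
    gap_step = gap * KS - 1
    match_step = match * KS + KM - 1
    mis_step = mismatch * KS - 1

    prev = [j * gap_step for j in range(m + 1)]
    cur = [0] * (m + 1)
    for i in range(1, n + 1):
        cur[0] = i * gap_step
        ai = a[i - 1]
        p = prev
        c = cur
        for j in range(1, m + 1):
            diag = p[j - 1] + (match_step if ai == b[j - 1] else mis_step)
            up = p[j] + gap_step
            left = c[j - 1] + gap_step
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            c[j] = best
        prev, cur = cur, prev
    enc = prev[m]
    # decode: enc = score*KS + matches*KM - columns with 1 <= columns <= 2L < KM
    # and 0 <= matches <= L < L+2, so the fields unpack by successive mod.
    columns = KM - (enc % KM)
    rest = (enc + columns) // KM  # = score*(L+2) + matches
    matches = rest % (L + 2)
    score = (rest - matches) // (L + 2)
    return score, matches, columns


def nw_identity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> float:
    """Identity fraction of the optimal global alignment: matches divided by
    alignment columns (gap columns count in the denominator)."""
    if a == b:
        return 1.0
    _, matches, columns = nw_align(a, b, match, mismatch, gap)
    return matches / columns


def nw_match_profile(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[np.ndarray, float]:
    """Per-query-position match indicator from the optimal global alignment.

    Returns ``(profile, identity)`` where ``profile[i]`` is True when query
    position ``i`` is aligned to an identical subject base (gapped or
    mismatched positions are False) and ``identity`` is the alignment
    identity as in :func:`nw_identity`. The same lexicographic tie-break as
    :func:`nw_align` applies, realized through the traceback preference
    diagonal > up > left.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    n, m = len(query), len(subject)
    L = n + m
    KM = 2 * L + 2
    KS = KM * (L + 2)
    gap_step = gap * KS - 1
    match_step = match * KS + KM - 1
    mis_step = mismatch * KS - 1

    prev = [j * gap_step for j in range(m + 1)]
    ptr: list[bytearray] = [bytearray([0] + [2] * m)]  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        cur[0] = i * gap_step
        prow = bytearray(m + 1)
        prow[0] = 1
        qi = query[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match_step if qi == subject[j - 1] else mis_step)
            up = prev[j] + gap_step
            left = cur[j - 1] + gap_step
            if diag >= up and diag >= left:
                cur[j] = diag
            elif up >= left:
                cur[j] = up
                prow[j] = 1
            else:
                cur[j] = left
                prow[j] = 2
        ptr.append(prow)
        prev = cur
    profile = np.zeros(n, dtype=bool)
    matches = 0
    columns = 0
    i, j = n, m
    while i > 0 or j > 0:
        columns += 1
        p = ptr[i][j]
        if p == 0 and i > 0 and j > 0:
            if query[i - 1] == subject[j - 1]:
                profile[i - 1] = True
                matches += 1
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            i -= 1
        else:
            j -= 1
    return profile, matches / columns


# ---------------------------------------------------------------------------
# chimera detection (simplified two-parent breakpoint model)
# ---------------------------------------------------------------------------


def detect_chimeras(
    isus: Sequence[ISU],
    parent_ratio: float = 2.0,
    identity_threshold: float = 0.99,
    scoring: tuple[int, int, int] = (1, -1, -2),
    max_parents: int = 20,
) -> list[bool]:
    """Flag ISUs explainable as a single-breakpoint splice of two more
    abundant parents.

    Scanning in descending abundance, a query is flagged when two parents,
    each at least ``parent_ratio`` times as abundant, admit a breakpoint
    splice whose identity to the query (computed over query coordinates from
    the parents' alignment match profiles) is >= ``identity_threshold`` and
    exceeds the query's best single-parent identity. At most ``max_parents``
    of the most abundant eligible parents are examined per query.
    """
    order = sorted(range(len(isus)), key=lambda k: (-isus[k].total, isus[k].sequence))
    flags = [False] * len(isus)
    for pos, k in enumerate(order):
        q = isus[k]
        if not q.sequence:
            continue
        parents = [
            isus[j]
            for j in order[:pos]
            if not flags[j]
            and isus[j].total >= parent_ratio * q.total
            and isus[j].sequence != q.sequence
        ][:max_parents]
        if len(parents) < 2:
            continue
        profiles = []
        best_single = 0.0
        for p in parents:
            prof, ident = nw_match_profile(q.sequence, p.sequence, *scoring)
            profiles.append(np.cumsum(prof))
            best_single = max(best_single, ident)
        Lq = len(q.sequence)
        totals = [int(c[-1]) for c in profiles]
        best_splice = 0
        for ia in range(len(parents)):
            ca = profiles[ia]
            for ib in range(len(parents)):
                if ia == ib:
                    continue
                # matches = prefix matches from parent A + suffix from parent B
                split = ca[:-1] + (totals[ib] - profiles[ib][:-1])
                if len(split):
                    best_splice = max(best_splice, int(split.max()))
        splice_identity = best_splice / Lq
        if splice_identity >= identity_threshold and splice_identity > best_single:
            flags[k] = True
    return flags


# ---------------------------------------------------------------------------
# taxonomic assignment and clustering
# ---------------------------------------------------------------------------


def _consensus_path(paths: Sequence[tuple[str, ...]]) -> tuple[str, ...]:
    """Deepest taxonomy prefix shared by all paths."""
    if not paths:
        return ()
    out: list[str] = []
    for levels in zip(*paths):
        if len(set(levels)) == 1:
            out.append(levels[0])
        else:
            break
    return tuple(out)


def assign_isu(
    isu: ISU,
    refdb: ReferenceDB,
    identity_floor: float = 0.80,
    scoring: tuple[int, int, int] = (1, -1, -2),
) -> tuple[tuple[str, ...] | None, float]:
    """Assign an ISU to the consensus taxonomy of its best-identity references.

    The best identity must be strictly above ``identity_floor``; otherwise the
    ISU is left unassigned. Exactly tied best hits contribute the deepest
    shared prefix of their taxonomy paths.
    """
    if len(refdb) == 0:
        raise ValueError("reference database is empty")
    best = -1.0
    best_paths: list[tuple[str, ...]] = []
    for rec in sorted(refdb, key=lambda r: (r.sequence, r.id)):
        ident = nw_identity(isu.sequence, rec.sequence, *scoring)
        if ident > best:
            best = ident
            best_paths = [rec.taxonomy]
        elif ident == best:
            best_paths.append(rec.taxonomy)
    if best <= identity_floor:
        return None, best
    return _consensus_path(best_paths), best


def precluster(isus: Sequence[ISU], signature_length: int = 30) -> dict[str, list[ISU]]:
    """Group ISUs by exact match of their 5' signature prefix.

    ISUs shorter than the signature use their full sequence.
    """
    groups: dict[str, list[ISU]] = {}
    for u in isus:
        groups.setdefault(u.sequence[:signature_length], []).append(u)
    return groups


def group_threshold(
    members: Sequence[ISU],
    default: float = 0.03,
    overrides: dict[str, float] | None = None,
) -> float:
    """Clustering threshold for a pre-cluster, from taxonomy-keyed overrides.

    The deepest taxonomy level of the members' consensus path that appears in
    ``overrides`` wins; otherwise the default applies.
    """
    if not overrides:
        return default
    consensus = _consensus_path([m.taxonomy for m in members if m.taxonomy])
    for level in reversed(consensus):
        if level in overrides:
            return overrides[level]
    return default


def cluster_otus(
    members: Sequence[ISU],
    threshold: float = 0.03,
    scoring: tuple[int, int, int] = (1, -1, -2),
) -> list[OTU]:
    """Average-linkage clustering of a pre-cluster at a distance threshold.

    Distances are 1 - NW identity; the dendrogram is cut where the average
    linkage height exceeds ``threshold``. Members are ordered
    lexicographically before clustering so distance ties resolve
    deterministically.
    """
    ms = sorted(members, key=lambda u: u.sequence)
    if len(ms) == 1:
        return [_make_otu(ms)]
    n = len(ms)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - nw_identity(ms[i].sequence, ms[j].sequence, *scoring)
            dm[i, j] = dm[j, i] = d
    Z = linkage(squareform(dm, checks=False), method="average")
    labels = fcluster(Z, t=threshold, criterion="distance")
    otus = []
    for lab in sorted(set(labels)):
        otus.append(_make_otu([ms[i] for i in range(n) if labels[i] == lab]))
    return otus


def _make_otu(members: list[ISU]) -> OTU:
    rep = min(members, key=lambda u: (-u.total, u.sequence)).sequence
    taxonomy = _consensus_path([m.taxonomy for m in members if m.taxonomy]) or None
    return OTU(members=list(members), representative=rep, taxonomy=taxonomy)


def classify_otu(
    otu: OTU,
    planktonic_refdb: ReferenceDB,
    otu_assign_identity: float = 0.95,
    scoring: tuple[int, int, int] = (1, -1, -2),
) -> OTU:
    """Set the habitat flag by exclusion against the planktonic references.

    The representative is assigned to a planktonic taxon iff its best
    identity to a planktonic reference is >= ``otu_assign_identity``
    (inclusive boundary); every other OTU is considered benthic.
    """
    best = -1.0
    best_paths: list[tuple[str, ...]] = []
    for rec in sorted(planktonic_refdb, key=lambda r: (r.sequence, r.id)):
        ident = nw_identity(otu.representative, rec.sequence, *scoring)
        if ident > best:
            best = ident
            best_paths = [rec.taxonomy]
        elif ident == best:
            best_paths.append(rec.taxonomy)
    if best >= otu_assign_identity:
        otu.habitat = "planktonic"
        otu.planktonic_taxon = _consensus_path(best_paths)
    else:
        otu.habitat = "benthic"
        otu.planktonic_taxon = None
    return otu


def filter_otus(otus: Sequence[OTU], min_samples: int = 3) -> list[OTU]:
    """Retain OTUs with nonzero counts in strictly more than ``min_samples`` samples."""
    return [
        o
        for o in otus
        if sum(1 for c in o.counts.values() if c > 0) > min_samples
    ]


def merge_variant_otus(otus: Sequence[OTU], enabled: bool = True) -> list[OTU]:
    """Merge planktonic OTUs sharing an identical species-level assignment.

    OTUs of one planktonic morphospecies are reported as a single unit
    (intragenomic rDNA variants); abundances are summed and the most
    abundant member OTU donates the representative. Disabled -> identity.
    """
    if not enabled:
        return list(otus)
    groups: dict[tuple[str, ...], list[OTU]] = {}
    out: list[OTU] = []
    for o in otus:
        if o.habitat == "planktonic" and o.planktonic_taxon and len(o.planktonic_taxon) == 6:
            groups.setdefault(o.planktonic_taxon, []).append(o)
        else:
            out.append(o)
    for taxon, group in groups.items():
        group = sorted(group, key=lambda o: (-o.total, o.representative))
        merged = OTU(
            members=[m for o in group for m in o.members],
            representative=group[0].representative,
            taxonomy=taxon,
            habitat="planktonic",
            planktonic_taxon=taxon,
        )
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    stage_counts: dict[str, int]
    isus: list[ISU]
    otus: list[OTU]
    retained: list[OTU]
    counts: pd.DataFrame
    taxonomy: pd.Series
    habitat: pd.Series


def run_pipeline(
    fastq_fwd,
    fastq_rev,
    tag_scheme: TagScheme,
    refdb: ReferenceDB,
    fwd_primer: str,
    rev_primer: str,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full chain from raw paired FASTQ to a filtered OTU table."""
    cfg = config or PipelineConfig()
    scoring = (cfg.nw_match, cfg.nw_mismatch, cfg.nw_gap)
    demux = Demultiplexer(tag_scheme, fwd_primer, rev_primer, cfg.tag_mismatch_max)

    counts = {
        "raw_pairs": 0,
        "quality_dropped": 0,
        "merge_rejected": 0,
        "demux_unassigned": 0,
        "demultiplexed": 0,
        "chimera_reads": 0,
        "assigned_reads": 0,
        "unassigned_reads": 0,
    }
    inserts: list[tuple[str, str]] = []
    for pair in read_fastq_pairs(fastq_fwd, fastq_rev):
        counts["raw_pairs"] += 1
        if not quality_filter(pair, cfg.mean_phred_min):
            counts["quality_dropped"] += 1
            continue
        merged = merge_pair(pair.seq_fwd, pair.seq_rev, cfg.min_overlap)
        if merged is None:
            counts["merge_rejected"] += 1
            continue
        sample, insert = demux(merged)
        if sample is None or not insert:
            counts["demux_unassigned"] += 1
            continue
        inserts.append((sample, insert))
    counts["demultiplexed"] = len(inserts)
    logger.info(
        "reads: %d raw, %d quality-dropped, %d merge-rejected, %d unassigned, %d demultiplexed",
        counts["raw_pairs"],
        counts["quality_dropped"],
        counts["merge_rejected"],
        counts["demux_unassigned"],
        counts["demultiplexed"],
    )

    isus = dereplicate(inserts)
    logger.info("dereplicated %d reads into %d ISUs", len(inserts), len(isus))

    chimera_flags = detect_chimeras(
        isus,
        cfg.chimera_parent_ratio,
        cfg.chimera_identity,
        scoring,
        cfg.chimera_max_parents,
    )
    counts["chimera_reads"] = sum(
        u.total for u, f in zip(isus, chimera_flags) if f
    )
    isus = [u for u, f in zip(isus, chimera_flags) if not f]
    logger.info(
        "chimera removal: %d ISUs flagged (%d reads)",
        sum(chimera_flags),
        counts["chimera_reads"],
    )

    for u in isus:
        u.taxonomy, u.best_identity = assign_isu(u, refdb, cfg.identity_floor, scoring)
    counts["assigned_reads"] = sum(u.total for u in isus if u.taxonomy)
    counts["unassigned_reads"] = sum(u.total for u in isus if not u.taxonomy)

    groups = precluster(isus, cfg.precluster_signature_length)
    otus: list[OTU] = []
    for sig in sorted(groups):
        thr = group_threshold(
            groups[sig], cfg.otu_distance_threshold, cfg.otu_threshold_overrides
        )
        otus.extend(cluster_otus(groups[sig], thr, scoring))
    logger.info("%d pre-clusters -> %d OTUs", len(groups), len(otus))

    planktonic_refs = refdb.planktonic_only()
    for o in otus:
        classify_otu(o, planktonic_refs, cfg.otu_assign_identity, scoring)

    retained = filter_otus(otus, cfg.min_samples_per_otu)
    if cfg.merge_variants:
        retained = merge_variant_otus(retained, True)
    logger.info("%d OTUs retained after the >%d-sample filter", len(retained), cfg.min_samples_per_otu)

    retained = sorted(retained, key=lambda o: (-o.total, o.representative))
    ids = [f"OTU_{i + 1:04d}" for i in range(len(retained))]
    table = pd.DataFrame(
        [[o.counts.get(s, 0) for s in tag_scheme.samples] for o in retained],
        index=ids,
        columns=tag_scheme.samples,
        dtype=int,
    )
    taxonomy = pd.Series(
        [";".join(o.taxonomy) if o.taxonomy else "unassigned" for o in retained],
        index=ids,
        name="taxonomy",
    )
    habitat = pd.Series([o.habitat for o in retained], index=ids, name="habitat")
    return PipelineResult(counts, isus, otus, retained, table, taxonomy, habitat)
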