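"""Synthetic sediment-core metabarcoding studies with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a reference barcode database of planktonic and benthic foraminifera in the
  37f length range, mutually separable at the OTU clustering threshold;
* depth-structured communities whose planktonic:benthic read mass follows
  the burial-decay model at the layer midpoint;
* a polar-vs-temperate compositional gradient through zone-specific base
  abundances (LC / transition / NAC);
* spinose-clade primer-mismatch dropout (taxa with forward-primer
  mismatches receive zero read mass);
* per-species amplification multipliers (rDNA copy-number bias) and a
  surface enrichment factor for designated taxa in the top layers;
* tagged paired-end reads with inline 8-nt Latin-square tag combinations,
  point errors, two-parent chimeras, and a per-read truth table;
* coupled microfossil census counts drawn from the same underlying
  assemblages, free of the molecular biases (spinose taxa present, no
  copy-number multiplier).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import DecayParams, fraction_profile
from .io import (
    DNA_ALPHABET,
    DesignError,
    ReferenceDB,
    RefRecord,
    TagScheme,
    revcomp,
    write_fastq_pair,
    write_metadata,
)

__all__ = [
    "TaxonSpec",
    "SimulationDesign",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
    "default_taxa",
    "default_design",
    "simulate_reference_db",
    "simulate_layer_community",
    "simulate_reads",
    "simulate_census",
    "simulate_study",
]

# synthetic stand-ins for the s14F1/s15 tagged primer pair
DEFAULT_FWD_PRIMER = "TCCGTAGGTGAACCTGC"
DEFAULT_REV_PRIMER = "GACGGGCGGTGTGTAC"


@dataclass
class TaxonSpec:
    """One simulated taxon and its amplification behaviour."""

    name: str
    habitat: str  # planktonic | benthic
    thermal: str = "transitional"  # polar | transitional | temperate | warm
    spinose: bool = False
    fwd_primer_mismatches: int = 0  # >=1 means the taxon never amplifies
    copy_number_multiplier: float = 1.0
    base_abundance: dict[str, float] = field(default_factory=dict)  # zone -> weight
    surface_enriched: bool = False

    def __post_init__(self) -> None:
        if self.spinose and self.fwd_primer_mismatches < 1:
            raise DesignError(f"spinose taxon {self.name} needs >=1 primer mismatch")
        if self.copy_number_multiplier <= 0:
            raise DesignError(f"non-positive multiplier for {self.name}")
        if any(v < 0 for v in self.base_abundance.values()):
            raise DesignError(f"negative base abundance for {self.name}")


@dataclass
class SimulationDesign:
    """Full layout of a synthetic study."""

    taxa: list[TaxonSpec]
    sites: dict[str, str]  # site -> zone
    layers: list[tuple[float, float]]  # (top_cm, bottom_cm), ordered, contiguous
    decay: DecayParams = field(default_factory=DecayParams)
    error_rate: float = 0.001
    chimera_rate: float = 0.01
    reads_per_sample: int = 2000
    replicates: int = 2
    surface_enrich_depth: float = 4.0  # cm; enrichment applies above this
    surface_enrich_factor: float = 10.0
    shell_ratio: float = 100.0  # planktonic:benthic shells in the census
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.error_rate, self.chimera_rate):
            if not 0 <= r <= 1:
                raise DesignError("rates must lie in [0, 1]")
        prev_bottom = 0.0
        for top, bottom in self.layers:
            if top != prev_bottom or bottom <= top:
                raise DesignError(
                    "layers must be ordered, non-overlapping and cover 0 to the core bottom"
                )
            prev_bottom = bottom
        if self.reads_per_sample <= 0:
            raise DesignError("reads_per_sample must be positive")
        if self.replicates < 1:
            raise DesignError("need at least one replicate per sample")

    @property
    def samples(self) -> list[tuple[str, tuple[float, float]]]:
        return [(site, layer) for site in self.sites for layer in self.layers]

    @property
    def sample_replicates(self) -> list[str]:
        """Replicate naming convention: ``<site>_<top>-<bottom>.rep<k>``."""
        out = []
        for site, (top, bottom) in self.samples:
            for k in range(1, self.replicates + 1):
                out.append(f"{site}_{top:g}-{bottom:g}.rep{k}")
        return out


def default_taxa(n_benthic: int = 20) -> list[TaxonSpec]:
    """Default taxon roster: the seven morphospecies detectable by the 37f
    assay, the two spinose dropouts, and ``n_benthic`` synthetic benthic taxa.

    Zone base abundances sketch the Newfoundland-margin gradient: polar (LC)
    assemblages dominated by N. pachyderma, temperate (NAC) assemblages with
    more transitional and warm taxa. G. inflata carries a 5x copy-number
    multiplier (rDNA over-representation); G. uvula is surface-enriched.
    """
    P = "planktonic"
    taxa = [
        TaxonSpec("Neogloboquadrina pachyderma", P, "polar",
                  base_abundance={"LC": 0.75, "transition": 0.40, "NAC": 0.10}),
        TaxonSpec("Neogloboquadrina incompta", P, "transitional",
                  base_abundance={"LC": 0.04, "transition": 0.15, "NAC": 0.20}),
        TaxonSpec("Globigerina bulloides", P, "transitional", spinose=True,
                  fwd_primer_mismatches=2,
                  base_abundance={"LC": 0.08, "transition": 0.20, "NAC": 0.25}),
        TaxonSpec("Turborotalita quinqueloba", P, "polar", spinose=True,
                  fwd_primer_mismatches=1,
                  base_abundance={"LC": 0.06, "transition": 0.10, "NAC": 0.08}),
        TaxonSpec("Globorotalia inflata", P, "temperate",
                  copy_number_multiplier=5.0,
                  base_abundance={"LC": 0.01, "transition": 0.08, "NAC": 0.22}),
        TaxonSpec("Globigerinita glutinata", P, "transitional",
                  base_abundance={"LC": 0.02, "transition": 0.04, "NAC": 0.06}),
        TaxonSpec("Globigerinita uvula", P, "transitional", surface_enriched=True,
                  base_abundance={"LC": 0.02, "transition": 0.02, "NAC": 0.04}),
        TaxonSpec("Globorotalia hirsuta", P, "warm",
                  base_abundance={"LC": 0.005, "transition": 0.005, "NAC": 0.03}),
        TaxonSpec("Tenuitella fleisheri", P, "transitional",
                  base_abundance={"LC": 0.005, "transition": 0.005, "NAC": 0.02}),
    ]
    for i in range(n_benthic):
        taxa.append(
            TaxonSpec(
                f"Benthic sp{i + 1:02d}",
                "benthic",
                base_abundance={z: 1.0 / n_benthic for z in ("LC", "transition", "NAC")},
            )
        )
    return taxa


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """Study-scale default: 4 sites across the hydrographic gradient,
    2-cm layers over 0-30 cm, 2 PCR replicates per sample."""
    kwargs = dict(
        taxa=default_taxa(),
        sites={
            "CoreLC1": "LC",
            "CoreLC2": "LC",
            "CoreTR1": "transition",
            "CoreNAC1": "NAC",
        },
        layers=[(float(t), float(t + 2)) for t in range(0, 30, 2)],
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------


def simulate_reference_db(
    n_planktonic: int = 9,
    n_benthic: int = 20,
    divergence: float = 0.2,
    seed: int = 0,
    taxa: Sequence[TaxonSpec] | None = None,
    length: int = 110,
    min_separation: float = 0.10,
    max_tries: int = 50,
) -> ReferenceDB:
    """Generate a synthetic taxonomy-annotated 37f barcode database.

    Each taxon's sequence is the common ancestor mutated at a fraction
    ``divergence`` of its positions; the construction is retried until every
    pair of taxa differs at more than ``min_separation`` of positions, which
    keeps distinct taxa separable at the OTU clustering threshold.

    When ``taxa`` is given, names/habitats come from the roster (overriding
    the counts); otherwise ``n_planktonic`` planktonic and ``n_benthic``
    benthic records with generic names are produced.
    """
    if not 0 < divergence < 0.5:
        raise DesignError("divergence must lie in (0, 0.5)")
    if taxa is None:
        if min(n_planktonic, n_benthic) < 1 and n_planktonic + n_benthic < 1:
            raise DesignError("need at least one taxon")
        taxa = [
            TaxonSpec(f"Planktic sp{i + 1:02d}", "planktonic")
            for i in range(n_planktonic)
        ] + [TaxonSpec(f"Benthic sp{i + 1:02d}", "benthic") for i in range(n_benthic)]
    rng = np.random.default_rng(seed)
    k = max(1, round(divergence * length))
    alphabet = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    for _ in range(max_tries):
        base = rng.integers(0, 4, size=length)
        seqs = []
        for _t in taxa:
            s = base.copy()
            pos = rng.choice(length, size=k, replace=False)
            s[pos] = (s[pos] + rng.integers(1, 4, size=k)) % 4
            seqs.append(s)
        mat = np.array(seqs)
        n = len(taxa)
        ok = True
        for i in range(n):
            diff = (mat[i] != mat[i + 1 :]).mean(axis=1) if i + 1 < n else []
            if len(diff) and diff.min() <= min_separation:
                ok = False
                break
        if ok:
            records = []
            for t, s in zip(taxa, seqs):
                genus, _, species = t.name.partition(" ")
                cls = "Globothalamea" if t.habitat == "planktonic" else "Monothalamea"
                records.append(
                    RefRecord(
                        id=t.name.replace(" ", "_"),
                        taxonomy=(
                            "Eukaryota",
                            "Rhizaria",
                            "Foraminifera",
                            cls,
                            genus,
                            species or "sp",
                        ),
                        habitat=t.habitat,
                        sequence="".join(
                            chr(alphabet[b]) for b in s
                        ),
                    )
                )
            return ReferenceDB(records)
    raise DesignError(
        f"could not separate {len(taxa)} taxa at divergence {divergence} "
        f"(min_separation {min_separation})"
    )


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------


def _layer_midpoint(layer: tuple[float, float]) -> float:
    return 0.5 * (layer[0] + layer[1])


def simulate_layer_community(
    design: SimulationDesign,
    site: str,
    layer: tuple[float, float],
) -> dict[str, float]:
    """Expected read proportions per taxon for one site/layer sample.

    The planktonic:benthic read mass split follows the decay model at the
    layer midpoint. Within the planktonic fraction, zone base abundances are
    weighted by copy-number multipliers and (above ``surface_enrich_depth``)
    the surface enrichment factor; taxa with forward-primer mismatches
    receive zero mass. The result sums to 1.
    """
    if site not in design.sites:
        raise DesignError(f"unknown site {site!r}")
    if layer not in design.layers:
        raise DesignError(f"layer {layer} not in design")
    zone = design.sites[site]
    z = _layer_midpoint(layer)
    frac = float(fraction_profile([z], design.decay).fraction[0])

    weights: dict[str, float] = {}
    for t in design.taxa:
        w = t.base_abundance.get(zone, 0.0)
        if t.habitat == "planktonic":
            if t.fwd_primer_mismatches >= 1:
                w = 0.0
            else:
                w *= t.copy_number_multiplier
                if t.surface_enriched and z < design.surface_enrich_depth:
                    w *= design.surface_enrich_factor
        weights[t.name] = w

    p_sum = sum(w for t, w in zip(design.taxa, weights.values()) if t.habitat == "planktonic")
    b_sum = sum(w for t, w in zip(design.taxa, weights.values()) if t.habitat == "benthic")
    out: dict[str, float] = {}
    p_mass = frac if p_sum > 0 else 0.0
    b_mass = 1.0 - frac if b_sum > 0 else 0.0
    norm = p_mass + b_mass
    if norm == 0:
        raise DesignError("community has zero total read mass")
    for t in design.taxa:
        w = weights[t.name]
        if t.habitat == "planktonic":
            out[t.name] = (p_mass / norm) * (w / p_sum) if p_sum > 0 else 0.0
        else:
            out[t.name] = (b_mass / norm) * (w / b_sum) if b_sum > 0 else 0.0
    return out


def expected_census_composition(
    design: SimulationDesign, zone: str
) -> dict[str, float]:
    """Zone-specific planktonic assemblage as the census sees it: spinose
    taxa present, no copy-number or surface bias."""
    planktonic = [t for t in design.taxa if t.habitat == "planktonic"]
    total = sum(t.base_abundance.get(zone, 0.0) for t in planktonic)
    if total <= 0:
        raise DesignError(f"zone {zone!r} has an empty planktonic assemblage")
    return {t.name: t.base_abundance.get(zone, 0.0) / total for t in planktonic}


def simulate_census(
    design: SimulationDesign,
    site: str,
    layer: tuple[float, float],
    n_tests: int = 250,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Census counts for one sample: a multinomial draw of ``n_tests``
    planktonic individuals plus benthic tests at the design's shell ratio.

    Returns ``(planktonic_counts, benthic_counts)``.
    """
    if n_tests < 1:
        raise DesignError("n_tests must be >= 1")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    zone = design.sites[site]
    comp = expected_census_composition(design, zone)
    names = list(comp)
    draws = rng.multinomial(n_tests, [comp[n] for n in names])
    planktonic = dict(zip(names, (int(x) for x in draws)))

    benthic_taxa = [t for t in design.taxa if t.habitat == "benthic"]
    n_benthic = int(rng.binomial(n_tests, 1.0 / design.shell_ratio))
    benthic: dict[str, int] = {t.name: 0 for t in benthic_taxa}
    if benthic_taxa and n_benthic:
        bw = np.array([t.base_abundance.get(zone, 0.0) for t in benthic_taxa])
        if bw.sum() == 0:
            bw[:] = 1.0
        bdraw = rng.multinomial(n_benthic, bw / bw.sum())
        benthic = {t.name: int(c) for t, c in zip(benthic_taxa, bdraw)}
    return planktonic, benthic


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    lut = {b: [o for o in b"ACGT" if o != b] for b in b"ACGT"}
    for i in hits:
        choices = lut.get(arr[i])
        if choices:
            arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_reads(
    design: SimulationDesign,
    refdb: ReferenceDB,
    out_dir: str | Path,
    tag_scheme: TagScheme | None = None,
    gzip_output: bool = False,
) -> dict[str, object]:
    """Generate the tagged paired-end FASTQ files and the per-read truth table.

    Each sample-replicate's reads are multinomial draws from its layer
    community; chimeric reads splice two abundance-weighted parent inserts at
    a uniform breakpoint. Amplicons carry the sample's tagged primers inline
    and are split into mates overlapping by at least 20 bases. Qualities are
    constant Q37. Returns paths, the tag scheme and the truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    seqs = {r.id.replace("_", " "): r.sequence for r in refdb}
    missing = [
        t.name
        for t in design.taxa
        if t.name not in seqs and t.fwd_primer_mismatches == 0
    ]
    if missing:
        raise DesignError(f"reference database lacks sequences for: {missing}")
    if tag_scheme is None:
        tag_scheme = TagScheme.latin_square(design.sample_replicates, seed=design.seed)
    else:
        covered = set(tag_scheme.samples)
        if not set(design.sample_replicates) <= covered:
            raise DesignError("tag scheme does not cover every sample-replicate")

    per_rep = design.reads_per_sample // design.replicates
    if per_rep < 1:
        raise DesignError("reads_per_sample too small for the replicate count")

    records: list[tuple[str, str, str]] = []
    truth_rows: list[tuple[str, str, str]] = []
    read_no = 0
    for site, layer in design.samples:
        community = simulate_layer_community(design, site, layer)
        names = [n for n, p in community.items() if p > 0]
        probs = np.array([community[n] for n in names])
        probs = probs / probs.sum()
        for k in range(1, design.replicates + 1):
            rep = f"{site}_{layer[0]:g}-{layer[1]:g}.rep{k}"
            ftag, rtag = tag_scheme.tags_for(rep)
            counts = rng.multinomial(per_rep, probs)
            inserts: list[tuple[str, str]] = []
            for name, c in zip(names, counts):
                inserts.extend([(name, seqs[name])] * int(c))
            perm = rng.permutation(len(inserts))
            inserts = [inserts[i] for i in perm]
            n_chim = int(rng.binomial(per_rep, design.chimera_rate)) if len(names) > 1 else 0
            for idx in range(per_rep):
                if idx < n_chim:
                    ia, ib = rng.choice(len(names), size=2, replace=False, p=probs)
                    sa, sb = seqs[names[ia]], seqs[names[ib]]
                    bp = int(rng.integers(1, min(len(sa), len(sb))))
                    insert = sa[:bp] + sb[bp:]
                    label = "chimera"
                else:
                    label, insert = inserts[idx]
                amplicon = (
                    ftag
                    + design.fwd_primer
                    + insert
                    + revcomp(rtag + design.rev_primer)
                )
                amplicon = _apply_errors(amplicon, design.error_rate, rng)
                rl = (len(amplicon) + 20 + 1) // 2
                rid = f"read{read_no:07d}"
                read_no += 1
                records.append((rid, amplicon[:rl], revcomp(amplicon[-rl:])))
                truth_rows.append((rid, rep, label))

    suffix = ".fastq.gz" if gzip_output else ".fastq"
    path_fwd = out_dir / f"reads_R1{suffix}"
    path_rev = out_dir / f"reads_R2{suffix}"
    write_fastq_pair(records, path_fwd, path_rev)
    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample", "taxon"])
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    tag_path = out_dir / "tags.tsv"
    tag_scheme.to_tsv(tag_path)
    return {
        "fastq_fwd": path_fwd,
        "fastq_rev": path_rev,
        "truth": truth,
        "truth_path": truth_path,
        "tag_scheme": tag_scheme,
        "tag_path": tag_path,
    }


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------


def metadata_frame(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for site, (top, bottom) in design.samples:
        for k in range(1, design.replicates + 1):
            rows.append(
                {
                    "sample": f"{site}_{top:g}-{bottom:g}.rep{k}",
                    "site": site,
                    "depth_cm_top": top,
                    "depth_cm_bottom": bottom,
                    "zone": design.sites[site],
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_study(
    design: SimulationDesign,
    out_dir: str | Path,
    n_tests: int = 250,
    refdb: ReferenceDB | None = None,
) -> dict[str, object]:
    """Write a complete synthetic study: reference FASTA, metadata, census
    table, tagged FASTQ pair, tag scheme and truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if refdb is None:
        refdb = simulate_reference_db(taxa=design.taxa, seed=design.seed)
    ref_path = out_dir / "reference.fasta"
    refdb.write_fasta(ref_path)

    meta = metadata_frame(design)
    write_metadata(meta, out_dir / "metadata.tsv")

    rng = np.random.default_rng(design.seed + 1)
    census_rows = []
    for site, layer in design.samples:
        plank, benth = simulate_census(design, site, layer, n_tests, rng)
        row = {"sample": f"{site}_{layer[0]:g}-{layer[1]:g}", **plank}
        row["benthic_tests"] = sum(benth.values())
        census_rows.append(row)
    census = pd.DataFrame(census_rows).set_index("sample").fillna(0).astype(int)
    census.to_csv(out_dir / "census.tsv", sep="\t")

    reads = simulate_reads(design, refdb, out_dir)
    return {
        "refdb": refdb,
        "reference_path": ref_path,
        "metadata": meta,
        "census": census,
        **reads,
    }
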