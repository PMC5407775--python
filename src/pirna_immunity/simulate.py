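"""Synthetic strains, genomes, small-RNA libraries, DNA-seq and phenotypes.

The generator emulates the statistical structure the analysis assumes:

* strain-specific primary piRNA production: cluster-derived reads are drawn
  at a rate proportional to the strain's ``primary_efficiency`` (epsilon),
  against a fixed background, so stronger primary processing raises the
  relative abundance of cluster-only transposon reads;
* ping-pong amplification: active transposons carry a steady-state read
  pool whose antisense "secondary" fraction (gamma / (1 + gamma)) is placed
  with its 5' end exactly 10 nt offset from a sense partner; the pool's
  total rate is epsilon-independent, mirroring amplification masking
  primary-efficiency differences for active elements;
* 24-29 nt piRNA lengths with a 1U bias enforced by resampling the first
  base (never by shifting coordinates), a 21-nt siRNA background, and
  random genome-derived 18-23 nt background reads;
* maternal transmission: embryo libraries thin every piRNA-derived source
  by the strain's ``maternal_transmission`` m and fill the deficit with
  background, so per-transposon RPM in embryos is m times the ovary value;
* DNA-seq coverage proportional to transposon copy number;
* a reactivity phenotype decreasing exponentially with ancestral-element
  piRNA abundance (the link function is a stand-in for the observed
  monotone negative correlation).

Every library records an analytic truth table of expected per-transposon
RPM so parameter-recovery tests have an independent oracle.  All
randomness flows from one integer seed; substreams are derived by stable
hashing of (strain, tissue, stage) tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp, substream
from .io import Library, SmallRNARead, TISSUES, write_bed, write_fasta, write_fastq, BedInterval
from .mapping import CanonicalTE, ClusterFragment, ClusterRegion
from .stats import ReactivityMeasure, reactivity

ANCESTRAL_TE = "I-like"
CHROM = "chr_sim"


# ---------------------------------------------------------------------------
# specifications and strain models
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class PanelSpec:
    """Canonical transposon panel parameters."""

    n_te: int = 5
    te_length: int = 1000
    gc: float = 0.45
    n_somatic: int = 1

    def __post_init__(self) -> None:
        if self.n_te < 1:
            raise ValueError("panel must contain at least one transposon")
        if self.te_length < 100:
            raise ValueError("canonical length must be >= 100 nt")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.n_somatic < 0 or self.n_somatic > self.n_te - 1:
            raise ValueError("n_somatic must leave room for the ancestral element")


@dataclass(slots=True)
class ClusterSpec:
    """Counts and sizing of the annotated cluster classes."""

    n_dual: int = 1
    n_uni_germline: int = 1
    n_uni_somatic: int = 1
    n_genic: int = 2
    genic_length: int = 800

    def __post_init__(self) -> None:
        for name in ("n_dual", "n_uni_germline", "n_uni_somatic", "n_genic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class StrainModel:
    """Synthetic-strain parameters (the recoverable ground truth)."""

    name: str
    primary_efficiency: float = 1.0  # epsilon
    pingpong_gain: float = 1.0  # gamma: secondary reads per primary, active TEs
    maternal_transmission: float = 1.0  # m
    te_copy_numbers: dict[str, int] = field(default_factory=dict)
    reactivity_slope: float = 0.001  # lambda
    reactivity_noise_sd: float = 2.0  # percentage points

    def __post_init__(self) -> None:
        if self.primary_efficiency <= 0:
            raise ValueError("primary_efficiency must be positive")
        if self.pingpong_gain < 0:
            raise ValueError("pingpong_gain must be non-negative")
        if not 0 <= self.maternal_transmission <= 1:
            raise ValueError("maternal_transmission must be in [0, 1]")
        if self.reactivity_slope < 0:
            raise ValueError("reactivity_slope must be non-negative")
        if self.reactivity_noise_sd < 0:
            raise ValueError("reactivity_noise_sd must be non-negative")
        for cn in self.te_copy_numbers.values():
            if cn < 0 or int(cn) != cn:
                raise ValueError("copy numbers must be non-negative integers")


@dataclass(slots=True)
class LibraryConfig:
    """Library composition weights (rates at epsilon = 1, summing with
    background to the sequencing budget)."""

    primary_weight: float = 0.02
    active_weight: float = 0.83
    sirna_fraction: float = 0.05
    background_fraction: float = 0.10
    p1u: float = 0.9
    error_rate: float = 0.001
    length_range: tuple[int, int] = (24, 29)


@dataclass
class SyntheticDataset:
    """A generated genome, panel, annotations, libraries and truth records."""

    genome: dict[str, str]
    te_panel: list[CanonicalTE]
    clusters: list[ClusterRegion]
    libraries: dict[tuple[str, str], Library] = field(default_factory=dict)
    dnaseq: dict[str, list[SmallRNARead]] = field(default_factory=dict)
    truth_strains: dict[str, StrainModel] = field(default_factory=dict)
    truth_rates: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    truth_dna: dict[str, pd.DataFrame] = field(default_factory=dict)
    seed: int | None = None

    @property
    def te_ids(self) -> list[str]:
        return [te.id for te in self.te_panel]

    def te(self, te_id: str) -> CanonicalTE:
        for te in self.te_panel:
            if te.id == te_id:
                return te
        raise KeyError(te_id)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/BED/FASTQ/TSV artifacts; returns {label: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        paths["te_panel"] = outdir / "te_panel.fa"
        write_fasta({te.id: te.sequence for te in self.te_panel}, paths["te_panel"])

        paths["clusters"] = outdir / "clusters.bed"
        write_bed(
            [
                BedInterval(c.chrom, c.start, c.end, f"{c.cluster_type}:{c.id}", 0,
                            c.strand if c.strand in "+-" else ".")
                for c in self.clusters
            ],
            paths["clusters"],
        )
        paths["fragments"] = outdir / "fragments.bed"
        write_bed(
            [
                BedInterval(c.chrom, f.start, f.end, f"{c.id}:{f.te_id}", 0, f.orientation)
                for c in self.clusters
                for f in c.fragments
            ],
            paths["fragments"],
        )

        for (strain, tissue), lib in self.libraries.items():
            key = f"smallrna_{strain}_{tissue}"
            paths[key] = outdir / f"{key}.fastq"
            write_fastq(lib.reads, paths[key])
        for strain, reads in self.dnaseq.items():
            key = f"dnaseq_{strain}"
            paths[key] = outdir / f"{key}.fastq"
            write_fastq(reads, paths[key])

        if self.truth_rates:
            frames = []
            for (strain, tissue), frame in sorted(self.truth_rates.items()):
                f = frame.copy()
                f.insert(0, "strain", strain)
                f.insert(1, "tissue", tissue)
                frames.append(f.reset_index())
            paths["truth_rates"] = outdir / "truth_rates.tsv"
            pd.concat(frames).to_csv(paths["truth_rates"], sep="\t", index=False)
        if self.truth_strains:
            rows = []
            for model in self.truth_strains.values():
                rows.append(
                    {
                        "strain": model.name,
                        "primary_efficiency": model.primary_efficiency,
                        "pingpong_gain": model.pingpong_gain,
                        "maternal_transmission": model.maternal_transmission,
                        "reactivity_slope": model.reactivity_slope,
                        "reactivity_noise_sd": model.reactivity_noise_sd,
                        **{f"cn_{k}": v for k, v in model.te_copy_numbers.items()},
                    }
                )
            paths["truth_strains"] = outdir / "truth_strains.tsv"
            pd.DataFrame(rows).to_csv(paths["truth_strains"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def simulate_genome(
    panel_spec: PanelSpec,
    cluster_spec: ClusterSpec,
    seed: int,
    tail_length: int = 2000,
) -> SyntheticDataset:
    """Build the panel, genome and cluster annotations for one dataset.

    The first panel entry is the ancestral element (``I-like``): inactive,
    zero full-length genomic copies, fragments only inside dual-strand
    clusters.  The last ``n_somatic`` entries are somatic elements with
    fragments only in the somatic uni-strand cluster; the rest are active
    germline elements.
    """
    if seed is None:
        raise ValueError("a seed is mandatory (reproducibility)")
    rng = substream(seed, "genome")

    panel: list[CanonicalTE] = []
    n_germline_active = panel_spec.n_te - 1 - panel_spec.n_somatic
    for i in range(panel_spec.n_te):
        seq = _random_seq(rng, panel_spec.te_length, panel_spec.gc)
        if i == 0:
            panel.append(CanonicalTE(ANCESTRAL_TE, seq, "germline", active=False))
        elif i <= n_germline_active:
            panel.append(CanonicalTE(f"TE_g{i}", seq, "germline", active=True))
        else:
            panel.append(
                CanonicalTE(f"TE_s{i - n_germline_active}", seq, "somatic", active=False)
            )
    germline_active = [te for te in panel if te.active]
    somatic = [te for te in panel if te.deposition_class == "somatic"]

    chunks: list[str] = []
    clusters: list[ClusterRegion] = []
    cursor = 0

    def _append(seq: str) -> int:
        nonlocal cursor
        chunks.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    def _spacer() -> None:
        _append(_random_seq(rng, int(rng.integers(500, 1500)), panel_spec.gc))

    def _fragment_cluster(
        cid: str, ctype: str, members: Sequence[CanonicalTE], strand: str
    ) -> None:
        _spacer()
        cluster_start = cursor
        fragments: list[ClusterFragment] = []
        for te in members:
            frac = rng.uniform(0.3, 0.8)
            flen = max(50, int(round(frac * te.length)))
            fstart = int(rng.integers(0, te.length - flen + 1))
            orientation = "+" if rng.random() < 0.5 else "-"
            sub = te.sequence[fstart : fstart + flen]
            if orientation == "-":
                sub = revcomp(sub)
            gstart = _append(sub)
            fragments.append(
                ClusterFragment(te.id, gstart, gstart + flen, fstart, fstart + flen, orientation)
            )
            _append(_random_seq(rng, int(rng.integers(20, 61)), panel_spec.gc))
        clusters.append(
            ClusterRegion(cid, CHROM, cluster_start, cursor, ctype, strand, fragments)
        )

    _spacer()
    for i in range(cluster_spec.n_dual):
        _fragment_cluster(f"dual{i + 1}", "dual", [panel[0]] + germline_active, ".")
    for i in range(cluster_spec.n_uni_germline):
        _fragment_cluster(
            f"uniG{i + 1}", "uni_germline", germline_active or [panel[0]], "+"
        )
    for i in range(cluster_spec.n_uni_somatic):
        if somatic:
            _fragment_cluster(f"uniS{i + 1}", "uni_somatic", somatic, "+")
    for i in range(cluster_spec.n_genic):
        _spacer()
        start = _append(_random_seq(rng, cluster_spec.genic_length, panel_spec.gc))
        clusters.append(
            ClusterRegion(f"genic{i + 1}", CHROM, start, cursor, "genic_3utr", "+")
        )
    _append(_random_seq(rng, max(100, tail_length), panel_spec.gc))

    return SyntheticDataset(
        genome={CHROM: "".join(chunks)},
        te_panel=panel,
        clusters=clusters,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# small-RNA library simulation
# ---------------------------------------------------------------------------

def _cluster_rates(dataset: SyntheticDataset, epsilon: float, cfg: LibraryConfig) -> dict[str, float]:
    total_len = sum(c.length for c in dataset.clusters)
    if total_len == 0:
        return {}
    return {
        c.id: epsilon * cfg.primary_weight * c.length / total_len for c in dataset.clusters
    }


def _active_rates(dataset: SyntheticDataset, cfg: LibraryConfig) -> dict[str, float]:
    active = [te for te in dataset.te_panel if te.active]
    total_len = sum(te.length for te in active)
    if total_len == 0:
        return {}
    return {te.id: cfg.active_weight * te.length / total_len for te in active}


def _force_first_base(
    seqs: list[str], mask: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Resample the 5' base: forced to T where mask, uniform A/C/G elsewhere."""
    alt = np.array(list("ACG"))
    out = []
    for i, s in enumerate(seqs):
        if mask[i]:
            out.append("T" + s[1:])
        else:
            out.append(alt[rng.integers(0, 3)] + s[1:])
    return out


def _inject_errors(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Per-base substitution errors at ``rate`` (single substitution drawn
    per affected read; adequate at the default 0.1% rate)."""
    if rate <= 0:
        return seqs
    bases = "ACGT"
    out = []
    for s in seqs:
        if rng.random() < rate * len(s):
            pos = int(rng.integers(0, len(s)))
            new = bases[int(rng.integers(0, 4))]
            if new == s[pos]:
                new = bases[(bases.index(new) + 1) % 4]
            s = s[:pos] + new + s[pos + 1 :]
        out.append(s)
    return out


def _expected_te_rates(
    dataset: SyntheticDataset,
    cluster_rates: Mapping[str, float],
    active_rates: Mapping[str, float],
    cfg: LibraryConfig,
) -> pd.Series:
    """Analytic expected mappable read rate per transposon.

    Cluster fragments contribute proportionally to the positions from which
    a 24-29 nt read maps back to the canonical sequence at <= 3 mismatches
    (fragment length - read length + 1, plus a 3 nt allowance per edge);
    the active-element pool contributes its full rate.
    """
    lengths = range(cfg.length_range[0], cfg.length_range[1] + 1)
    rates = {te.id: 0.0 for te in dataset.te_panel}
    for cluster in dataset.clusters:
        rate_c = cluster_rates.get(cluster.id, 0.0)
        if rate_c == 0 or cluster.length == 0:
            continue
        for frag in cluster.fragments:
            flen = frag.end - frag.start
            mappable = np.mean(
                [max(0, min(flen - L + 1 + 6, cluster.length - L + 1)) for L in lengths]
            )
            rates[frag.te_id] += rate_c * mappable / max(1, cluster.length - np.mean(lengths) + 1)
    for te_id, rate in active_rates.items():
        rates[te_id] += rate
    return pd.Series(rates).sort_index()


def simulate_small_rna_library(
    dataset: SyntheticDataset,
    strain: StrainModel,
    tissue: str,
    n_reads: int,
    seed: int,
    config: LibraryConfig | None = None,
) -> Library:
    """Draw one ovary or 0-2 h embryo small-RNA library for a strain.

    The library is a multinomial draw over sources: cluster-primary reads
    (rate epsilon-scaled), the active-element steady-state pool with its
    gamma-controlled antisense secondary fraction, 21-nt siRNAs, and
    genome-derived background; embryo tissue thins all piRNA sources by the
    maternal-transmission fraction.  The per-transposon truth table is
    stored on the dataset.
    """
    if tissue not in TISSUES:
        raise ValueError(f"tissue must be one of {TISSUES}")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    cfg = config or LibraryConfig()
    if not 0 <= cfg.p1u <= 1:
        raise ValueError("p1u must be in [0, 1]")
    for te_id in strain.te_copy_numbers:
        if te_id not in dataset.te_ids:
            raise ValueError(f"copy number given for unknown transposon {te_id!r}")
    rng = substream(seed, strain.name, tissue, "smallrna")

    m = strain.maternal_transmission if tissue == "embryo_0_2h" else 1.0
    cluster_rates = {k: m * v for k, v in _cluster_rates(dataset, strain.primary_efficiency, cfg).items()}
    active_rates = {k: m * v for k, v in _active_rates(dataset, cfg).items()}
    sirna_rate = m * cfg.sirna_fraction
    pirna_total = sum(cluster_rates.values()) + sum(active_rates.values()) + sirna_rate
    # Background fills the sequencing budget, so per-source sampling
    # probabilities equal the rates while pirna_total <= 1; beyond that the
    # budget renormalizes everything (recorded in the truth table).
    background_rate = max(0.0, 1.0 - pirna_total)
    budget = max(1.0, pirna_total)

    sources: list[tuple[str, str, float]] = []
    for cid, rate in cluster_rates.items():
        sources.append(("cluster", cid, rate))
    for te_id, rate in active_rates.items():
        sources.append(("active", te_id, rate))
    sources.append(("sirna", "", sirna_rate))
    sources.append(("background", "", background_rate))
    probs = np.array([s[2] for s in sources])
    probs = probs / probs.sum()
    source_counts = rng.multinomial(n_reads, probs)

    cluster_by_id = {c.id: c for c in dataset.clusters}
    genome_seq = dataset.genome[CHROM]
    lo, hi = cfg.length_range
    seqs: list[str] = []

    for (kind, name, _), count in zip(sources, source_counts):
        if count == 0:
            continue
        if kind == "cluster":
            cluster = cluster_by_id[name]
            cseq = genome_seq[cluster.start : cluster.end]
            lengths = rng.integers(lo, hi + 1, size=count)
            lengths = np.minimum(lengths, len(cseq))
            starts = (rng.random(count) * (len(cseq) - lengths + 1)).astype(int)
            if cluster.cluster_type == "dual":
                strands = rng.random(count) < 0.5
            else:
                strands = np.full(count, cluster.strand != "-")
            batch = []
            for s, L, plus in zip(starts, lengths, strands):
                sub = cseq[s : s + L]
                batch.append(sub if plus else revcomp(sub))
            batch = _force_first_base(batch, rng.random(count) < cfg.p1u, rng)
            seqs.extend(batch)
        elif kind == "active":
            te = dataset.te(name)
            gamma = strain.pingpong_gain
            n_sec = rng.binomial(count, gamma / (1.0 + gamma)) if gamma > 0 else 0
            n_sense = count - n_sec
            sense_len = rng.integers(lo, hi + 1, size=n_sense)
            sense_start = (rng.random(n_sense) * (te.length - sense_len + 1)).astype(int)
            batch = [
                te.sequence[s : s + L] for s, L in zip(sense_start, sense_len)
            ]
            batch = _force_first_base(batch, rng.random(n_sense) < cfg.p1u, rng)
            seqs.extend(batch)
            if n_sec:
                sec_len = rng.integers(lo, hi + 1, size=n_sec)
                if n_sense:
                    partners = sense_start[rng.integers(0, n_sense, size=n_sec)]
                else:
                    partners = rng.integers(0, te.length - 10, size=n_sec)
                # clamp the partner 5' so the antisense span stays in bounds
                partners = np.clip(partners, sec_len - 10, te.length - 10)
                five_prime = partners + 9
                for q, L in zip(five_prime, sec_len):
                    seqs.append(revcomp(te.sequence[q - L + 1 : q + 1]))
        elif kind == "sirna":
            pool = [genome_seq[c.start : c.end] for c in dataset.clusters] or [genome_seq]
            which = rng.integers(0, len(pool), size=count)
            for w in which:
                src = pool[w]
                L = min(21, len(src))
                s = int(rng.integers(0, len(src) - L + 1))
                sub = src[s : s + L]
                seqs.append(sub if rng.random() < 0.5 else revcomp(sub))
        else:  # background
            lengths = rng.integers(18, 24, size=count)
            starts = (rng.random(count) * (len(genome_seq) - lengths + 1)).astype(int)
            for s, L in zip(starts, lengths):
                sub = genome_seq[s : s + L]
                seqs.append(sub if rng.random() < 0.5 else revcomp(sub))

    seqs = _inject_errors(seqs, cfg.error_rate, rng)
    order = rng.permutation(len(seqs))
    reads = [
        SmallRNARead(f"{strain.name}_{tissue}_r{i:07d}", seqs[j])
        for i, j in enumerate(order)
    ]
    library = Library(strain=strain.name, tissue=tissue, reads=reads, depth=n_reads)

    truth = (_expected_te_rates(dataset, cluster_rates, active_rates, cfg) / budget).to_frame("rate")
    truth["expected_rpm"] = truth["rate"] * 1e6
    dataset.truth_rates[(strain.name, tissue)] = truth
    dataset.truth_strains[strain.name] = strain
    dataset.libraries[(strain.name, tissue)] = library
    return library


# ---------------------------------------------------------------------------
# DNA-seq simulation
# ---------------------------------------------------------------------------

def simulate_dnaseq(
    dataset: SyntheticDataset,
    strain: StrainModel,
    n_reads: int,
    read_len: int = 50,
    seed: int = 0,
    error_rate: float = 0.001,
) -> list[SmallRNARead]:
    """Uniform whole-genome reads from the strain genome.

    The strain genome is the shared base genome (with its cluster-embedded
    fragments) plus ``te_copy_numbers`` full-length copies of each
    transposon, so expected per-element DNA RPM tracks copy number and
    fragment content.
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    for te_id in strain.te_copy_numbers:
        if te_id not in dataset.te_ids:
            raise ValueError(f"copy number given for unknown transposon {te_id!r}")
    rng = substream(seed, strain.name, "dnaseq")

    segments = [dataset.genome[CHROM]]
    for te in dataset.te_panel:
        for _ in range(strain.te_copy_numbers.get(te.id, 0)):
            segments.append(_random_seq(rng, 40, 0.45))
            segments.append(te.sequence)
    strain_genome = "".join(segments)

    n_pos = len(strain_genome) - read_len + 1
    starts = (rng.random(n_reads) * n_pos).astype(int)
    seqs = []
    for s in starts:
        sub = strain_genome[s : s + read_len]
        seqs.append(sub if rng.random() < 0.5 else revcomp(sub))
    seqs = _inject_errors(seqs, error_rate, rng)
    reads = [
        SmallRNARead(f"{strain.name}_dna_r{i:07d}", seq) for i, seq in enumerate(seqs)
    ]

    rates = {}
    for te in dataset.te_panel:
        cn = strain.te_copy_numbers.get(te.id, 0)
        positions = cn * (te.length - read_len + 1 + 6)
        for cluster in dataset.clusters:
            for frag in cluster.fragments:
                if frag.te_id == te.id:
                    positions += max(0, (frag.end - frag.start) - read_len + 1 + 6)
        rates[te.id] = positions / n_pos
    truth = pd.Series(rates).sort_index().to_frame("rate")
    truth["expected_rpm"] = truth["rate"] * 1e6
    dataset.truth_dna[strain.name] = truth
    dataset.dnaseq[strain.name] = reads
    dataset.truth_strains.setdefault(strain.name, strain)
    return reads


# ---------------------------------------------------------------------------
# reactivity simulation
# ---------------------------------------------------------------------------

def simulate_reactivity(
    strain: StrainModel,
    i_pirna_rpm: float,
    seed: int,
    n_replicates: int = 3,
    embryos_per_replicate: int = 100,
) -> ReactivityMeasure:
    """Percent non-hatching embryos decreasing with ancestral piRNA abundance.

    reactivity = clamp(100 * exp(-lambda * rpm) + Normal(0, noise_sd), 0, 100)
    per replicate; replicates are returned as (non-hatched, total) counts.
    """
    if i_pirna_rpm < 0:
        raise ValueError("piRNA abundance must be non-negative")
    if strain.reactivity_slope < 0:
        raise ValueError("reactivity slope must be non-negative")
    rng = substream(seed, strain.name, "reactivity")
    base = 100.0 * math.exp(-strain.reactivity_slope * i_pirna_rpm)
    replicates = []
    for _ in range(n_replicates):
        pct = base + rng.normal(0.0, strain.reactivity_noise_sd) if strain.reactivity_noise_sd > 0 else base
        pct = min(100.0, max(0.0, pct))
        non_hatched = int(round(pct / 100.0 * embryos_per_replicate))
        replicates.append((non_hatched, embryos_per_replicate))
    return reactivity(replicates, strain=strain.name)
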