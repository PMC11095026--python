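"""End-to-end orchestration: digest -> combine -> size-select -> allocate ->
write FASTQ, and the reverse quantification path (recreate -> cut-efficiency
-> FLTR).  One master seed drives every random stream, so identical
configuration yields byte-identical outputs."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .digestion import (
    DigestionParams,
    build_cut_map,
    digest_genome,
    fragments_to_frame,
)
from .estimation import (
    DEFAULT_MIN_INNER_COUNT,
    DEFAULT_WINDOW,
    CutEfficiencyEstimate,
    estimate_cut_efficiency,
    find_encompassment_pairs,
)
from .fltr import (
    FltrResult,
    baseline_estimates,
    compute_ratio_matrix,
    depth_by_length,
    fltr_estimate,
    recreate_fragments,
)
from .genome_io import (
    CommunityProfile,
    EnzymeMotif,
    GenomeRecord,
    load_abundance_table,
    load_genomes,
    parse_motif_arg,
)
from .sequencing import (
    AdapterSet,
    QualityProfile,
    load_quality_profile,
    simulate_read_pairs,
    write_fastq,
)
from .size_selection import (
    LengthDistribution,
    SimulationConfig,
    SizeSelectionParams,
    allocate_reads,
    combine_by_abundance,
    envelope_curve,
    gaussian_envelope,
)

__all__ = [
    "SimulationResult",
    "QuantificationResult",
    "run_simulation",
    "run_quantification",
    "run_pipeline",
]


@dataclass
class SimulationResult:
    fragments: pd.DataFrame  # per-fragment weights and allocated read counts
    dist_digest: LengthDistribution
    dist_selected: LengthDistribution
    cut_map: dict[tuple[str, str], list[int]]
    r1_path: Path | None
    r2_path: Path | None
    n_written: int


@dataclass
class QuantificationResult:
    table: pd.DataFrame  # taxon-level abundance estimates
    fltr: FltrResult
    ratio_matrix: pd.DataFrame
    cut_efficiency: CutEfficiencyEstimate
    observed: pd.DataFrame


def _check_ids(records: list[GenomeRecord]) -> None:
    for rec in records:
        if ":" in rec.genome_id or ":" in rec.id:
            raise ValueError(
                f"':' is reserved for provenance read names "
                f"(genome {rec.genome_id!r}, contig {rec.id!r})"
            )


def run_simulation(
    records: list[GenomeRecord],
    profile: CommunityProfile,
    motifs: list[EnzymeMotif],
    digestion_params: DigestionParams,
    size_params: SizeSelectionParams,
    config: SimulationConfig,
    outdir: str | Path | None = None,
    adapters: AdapterSet | None = None,
    quality_profile: QualityProfile | None = None,
    forward_enzyme: str | None = None,
    mutate: bool = True,
) -> SimulationResult:
    """Simulate an RMS library for a community.

    Digest every genome of the profile, scale by abundance, size-select,
    allocate the read budget and (when ``outdir`` is given) write paired
    provenance-annotated FASTQ.
    """
    _check_ids(records)
    by_genome: dict[str, list[GenomeRecord]] = {}
    for rec in records:
        by_genome.setdefault(rec.genome_id, []).append(rec)
    per_genome = {}
    for genome_id in profile.genome_ids:
        if genome_id not in by_genome:
            raise ValueError(f"abundance table names unknown genome {genome_id!r}")
        fragments, _dist = digest_genome(by_genome[genome_id], motifs, digestion_params)
        per_genome[genome_id] = fragments
    D, weighted = combine_by_abundance(per_genome, profile)
    if len(D) == 0:
        raise ValueError("digestion produced no fragments in the size window")
    S = gaussian_envelope(D, size_params)
    seed_alloc, seed_reads = np.random.SeedSequence(config.seed).spawn(2)
    counts = allocate_reads(S, weighted, config, rng=np.random.default_rng(seed_alloc))
    if forward_enzyme is None and len(motifs) > 1 and digestion_params.ddrad_strict:
        forward_enzyme = motifs[0].name
    sequences = {(rec.genome_id, rec.id): rec.sequence for rec in records}
    pairs = simulate_read_pairs(
        list(zip((f for f, _ in weighted), (int(c) for c in counts))),
        sequences,
        config.read_length,
        rng=np.random.default_rng(seed_reads),
        adapters=adapters,
        quality_profile=quality_profile,
        forward_enzyme=forward_enzyme,
        mutate=mutate,
    )
    table = fragments_to_frame([f for f, _ in weighted])
    table["weight"] = [w for _, w in weighted]
    table["read_count"] = np.asarray(counts, dtype=np.int64)
    cut_map = build_cut_map(records, motifs)
    r1_path = r2_path = None
    n_written = len(pairs)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        r1_path = outdir / "reads_R1.fastq"
        r2_path = outdir / "reads_R2.fastq"
        write_fastq(pairs, r1_path, r2_path)
        table.to_csv(outdir / "fragments.tsv", sep="\t", index=False)
        env, _anchor = envelope_curve(D, size_params)
        report = pd.DataFrame(
            {
                "length": D.support,
                "digest_count": [D[x] for x in D.support],
                "envelope": [env[x] for x in D.support],
                "selected": [S[x] for x in D.support],
            }
        )
        report.to_csv(outdir / "size_selection.tsv", sep="\t", index=False)
        _write_manifest(
            outdir,
            config=config,
            digestion_params=digestion_params,
            size_params=size_params,
            motifs=motifs,
            profile=profile,
            outputs=[r1_path, r2_path, outdir / "fragments.tsv"],
        )
    return SimulationResult(
        fragments=table,
        dist_digest=D,
        dist_selected=S,
        cut_map=cut_map,
        r1_path=r1_path,
        r2_path=r2_path,
        n_written=n_written,
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_manifest(outdir: Path, **sections) -> Path:
    manifest: dict = {"rmsim_version": __version__}
    config = sections.pop("config")
    manifest["config"] = asdict(config)
    manifest["digestion"] = asdict(sections.pop("digestion_params"))
    size_params = sections.pop("size_params")
    manifest["size_selection"] = {
        "mean": size_params.mean,
        "sd": size_params.sd,
        "anchor_length": size_params.anchor_length,
        "custom_weights": size_params.custom_weights is not None,
    }
    manifest["motifs"] = [asdict(m) for m in sections.pop("motifs")]
    manifest["community"] = dict(sections.pop("profile").entries)
    manifest["checksums"] = {
        path.name: _sha256(path) for path in sections.pop("outputs")
    }
    path = outdir / "manifest.json"
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return path


def expected_fragment_table(
    records: list[GenomeRecord],
    motifs: list[EnzymeMotif],
    digestion_params: DigestionParams,
) -> pd.DataFrame:
    """Enumerable fully digested (i = 0) fragments — the denominator
    population for depth-by-length and the baselines."""
    frames = []
    by_genome: dict[str, list[GenomeRecord]] = {}
    for rec in records:
        by_genome.setdefault(rec.genome_id, []).append(rec)
    for genome_id, contigs in by_genome.items():
        fragments, _ = digest_genome(contigs, motifs, digestion_params)
        frame = fragments_to_frame([f for f in fragments if f.i == 0])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_quantification(
    source: str | Path,
    records: list[GenomeRecord],
    motifs: list[EnzymeMotif],
    digestion_params: DigestionParams,
    taxon_of: dict[str, str] | None = None,
    outdir: str | Path | None = None,
    estimation_window: tuple[int, int] = DEFAULT_WINDOW,
    min_inner_count: float = DEFAULT_MIN_INNER_COUNT,
) -> QuantificationResult:
    """Recreate fragments from reads (provenance FASTQ or paired SAM),
    estimate cut efficiency, and quantify taxa with FLTR plus the mean- and
    median-depth baselines."""
    if taxon_of is None:
        taxon_of = {rec.genome_id: rec.genome_id for rec in records}
    cut_map = build_cut_map(records, motifs)
    ref_to_genome = None
    if str(source).endswith(".sam"):
        ref_to_genome = {rec.id: (rec.genome_id, rec.id) for rec in records}
    # cut-efficiency estimation needs the encompassing (i >= 1) fragments,
    # so recreate with internal-cut fragments kept and filter afterwards
    observed_all = recreate_fragments(
        source, cut_map, ref_to_genome=ref_to_genome, keep_internal=True
    )
    observed = observed_all[observed_all["i"] == 0].reset_index(drop=True)
    expected = expected_fragment_table(records, motifs, digestion_params)
    pairs = find_encompassment_pairs(
        observed_all, cut_map, window=estimation_window, min_inner_count=min_inner_count
    )
    efficiency = estimate_cut_efficiency(pairs)
    depth = depth_by_length(observed, expected, taxon_of)
    R = compute_ratio_matrix(depth)
    fltr = fltr_estimate(R)
    baselines = baseline_estimates(observed, expected, taxon_of)
    table = baselines.copy()
    table.insert(0, "fltr_abundance", fltr.abundances)
    table = table.rename(
        columns={"mean_depth": "mean_depth_abundance", "median_depth": "median_depth_abundance"}
    )
    table["quantified"] = table.index.isin(fltr.abundances.index)
    table.index.name = "taxon"
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "abundance_estimates.tsv", sep="\t")
        R.to_csv(outdir / "ratio_matrix.tsv", sep="\t")
        observed.to_csv(outdir / "recreated_fragments.tsv", sep="\t", index=False)
    return QuantificationResult(
        table=table,
        fltr=fltr,
        ratio_matrix=R,
        cut_efficiency=efficiency,
        observed=observed,
    )


def run_pipeline(config_path: str | Path) -> tuple[SimulationResult, QuantificationResult | None]:
    """Run simulation (and optional quantification) from a TOML config.

    Sections: [community] genomes (list of FASTA paths), abundance (TSV
    path); [enzymes] motifs (list of "NAME=G/AATTC" strings); [digest];
    [size_selection]; [sequencing] n, read_length, q_profile, adapters;
    [output] dir; [quantify] enabled.  Top-level key ``seed``.
    """
    with open(config_path, "rb") as handle:
        cfg = tomllib.load(handle)
    seed = int(cfg.get("seed", 1))
    community = cfg["community"]
    records = load_genomes(community["genomes"])
    profile = load_abundance_table(community["abundance"], records)
    motifs = [parse_motif_arg(m) for m in cfg["enzymes"]["motifs"]]
    dig = cfg.get("digest", {})
    dparams = DigestionParams(
        c=float(dig.get("c", 0.9)),
        length_min=int(dig.get("length_min", 1)),
        length_max=int(dig.get("length_max", 450)),
        ddrad_strict=bool(dig.get("ddrad_strict", False)),
        max_internal=int(dig.get("max_internal", 5)),
    )
    sel = cfg.get("size_selection", {})
    custom = (
        LengthDistribution.from_json(sel["custom_json"]) if "custom_json" in sel else None
    )
    sparams = SizeSelectionParams(
        mean=float(sel.get("mean", 150.0)),
        sd=float(sel.get("sd", 50.0)),
        anchor_length=sel.get("anchor", "auto"),
        custom_weights=custom,
    )
    seq = cfg.get("sequencing", {})
    config = SimulationConfig(
        n=int(seq.get("n", 100_000)),
        read_length=int(seq.get("read_length", 150)),
        seed=seed,
        rounding=seq.get("rounding", "multinomial"),
    )
    qprofile = (
        load_quality_profile(seq["q_profile"], config.read_length)
        if "q_profile" in seq
        else None
    )
    adapters = AdapterSet(
        r1_adapter=seq.get("r1_adapter", ""), r2_adapter=seq.get("r2_adapter", "")
    )
    outdir = Path(cfg.get("output", {}).get("dir", "rmsim_out"))
    sim = run_simulation(
        records,
        profile,
        motifs,
        dparams,
        sparams,
        config,
        outdir=outdir,
        adapters=adapters,
        quality_profile=qprofile,
    )
    quant = None
    if cfg.get("quantify", {}).get("enabled", False):
        quant = run_quantification(
            sim.r1_path, records, motifs, dparams, outdir=outdir
        )
    return sim, quant
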