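"""End-to-end orchestration: simulate/load → stats → AMOVA → tree/PCA →
admixture scan → fingerprints, with a run manifest for reproducibility."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .admixture import assign_groups, evanno_delta_k, run_k_scan
from .amova import amova
from .clustering import (
    nei_distance_matrix,
    pca,
    shared_allele_distance_matrix,
    upgma,
)
from .diversity import allele_frequencies, locus_statistics, population_statistics
from .fingerprint import (
    build_codebook,
    encode_fingerprints,
    find_duplicates,
    records_to_tsv,
    select_core_markers,
)
from .io_genotypes import GenotypeMatrix, read_genotype_table, write_genotype_table
from .synthetic_data import simulate_genotypes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full pipeline run.

    Either ``genotype_table`` points at an existing table, or the simulation
    block is used to generate one. Defaults follow the package's standard
    settings: K scan 1–10 with 10 replicates, 999 AMOVA permutations,
    duplicate threshold 1 locus, Q cutoffs 0.6/0.9.
    """

    outdir: str = "ssrkit_run"
    seed: int = 0
    genotype_table: str | None = None
    delimiter: str = "\t"
    # simulation block (used when genotype_table is None)
    sim_K: int = 2
    sim_n_loci: int = 20
    sim_alleles_per_locus: int = 6
    sim_n_per_pop: list[int] = field(default_factory=lambda: [40, 40])
    sim_motif_len: int = 3
    sim_freq_concentration: float = 0.3
    sim_admixture_alpha: float = 0.05
    sim_missing_rate: float = 0.0
    # analysis settings
    amova_permutations: int = 999
    k_min: int = 1
    k_max: int = 10
    structure_replicates: int = 10
    structure_reps: int = 2000
    structure_burnin: int = 500
    duplicate_max_loci: int = 1
    q_thresholds: list[float] = field(default_factory=lambda: [0.6, 0.9])

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.structure_replicates < 1 or self.amova_permutations < 0:
            raise ValueError("replicate/permutation counts must be valid")
        if any(not (0 < t < 1) for t in self.q_thresholds):
            raise ValueError("Q thresholds must lie in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Load a ``key = value`` config file; unknown keys are an error."""
    kwargs: dict = {}
    valid = set(RunConfig.__dataclass_fields__)
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"{path}:{ln}: unknown setting {key!r}")
        ftype = RunConfig.__dataclass_fields__[key].type
        if "list[int]" in str(ftype):
            kwargs[key] = [int(x) for x in val.split(",")]
        elif "list[float]" in str(ftype):
            kwargs[key] = [float(x) for x in val.split(",")]
        elif "int" in str(ftype):
            kwargs[key] = int(val)
        elif "float" in str(ftype):
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all outputs under ``config.outdir``.

    Returns the manifest dict. Any stage failure raises ``RuntimeError``
    naming the stage. Idempotent given the seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ssrkit_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
        "warnings": {},
    }

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - abort with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest["stages"].append(name)
        return result

    def _input() -> GenotypeMatrix:
        if config.genotype_table:
            gm = read_genotype_table(config.genotype_table, delimiter=config.delimiter)
            manifest["warnings"]["parse"] = gm.parse_warnings
            return gm
        gm, truth = simulate_genotypes(
            K=config.sim_K,
            n_loci=config.sim_n_loci,
            alleles_per_locus=config.sim_alleles_per_locus,
            n_per_pop=config.sim_n_per_pop,
            motif_len=config.sim_motif_len,
            freq_concentration=config.sim_freq_concentration,
            admixture_alpha=config.sim_admixture_alpha,
            missing_rate=config.sim_missing_rate,
            seed=config.seed,
        )
        write_genotype_table(gm, out / "genotypes.tsv")
        truth.to_json(out / "genotypes.truth.json")
        return gm

    gm = stage("input", _input)

    def _stats():
        stats = locus_statistics(gm)
        stats.round(4).to_csv(out / "locus_stats.tsv", sep="\t")
        pops = population_statistics(gm)
        pops.round(4).to_csv(out / "population_stats.tsv", sep="\t")
        return stats

    stats = stage("diversity", _stats)

    def _amova():
        res = amova(gm, n_permutations=config.amova_permutations, seed=config.seed)
        df = res.to_dataframe()
        df.to_csv(out / "amova.tsv", sep="\t", index=False)
        (out / "amova_summary.json").write_text(
            json.dumps(
                {
                    "phi_pt": res.phi_pt,
                    "nm": res.nm,
                    "p_value": res.p_value,
                    "pct_among": res.pct_among,
                    "pct_within": res.pct_within,
                }
            )
        )
        return res

    stage("amova", _amova)

    def _tree():
        dm = shared_allele_distance_matrix(gm)
        dm.to_tsv(out / "shared_allele_distances.tsv")
        tree = upgma(dm)
        (out / "upgma_accessions.nwk").write_text(tree.to_newick() + "\n")
        freqs = allele_frequencies(gm, by_population=True)
        if len(freqs.by_population) >= 2:
            ndm = nei_distance_matrix(freqs.by_population)
            ndm.to_tsv(out / "nei_population_distances.tsv")
            if len(ndm.labels) >= 2:
                ptree = upgma(ndm)
                (out / "upgma_populations.nwk").write_text(ptree.to_newick() + "\n")

    stage("tree", _tree)

    def _pca():
        coords, frac = pca(gm)
        with open(out / "pca.tsv", "w", encoding="utf-8") as fh:
            fh.write("accession\tpopulation\tPC1\tPC2\n")
            for (acc, pop), xy in zip(gm.accessions, coords[:, :2]):
                fh.write(f"{acc}\t{pop}\t{xy[0]:.6g}\t{xy[1]:.6g}\n")
        manifest["pca_explained"] = [float(f) for f in frac[:2]]

    stage("pca", _pca)

    def _structure():
        ks = list(range(config.k_min, config.k_max + 1))
        lnpd_runs, fits = run_k_scan(
            gm,
            ks,
            replicates=config.structure_replicates,
            reps=config.structure_reps,
            burnin=config.structure_burnin,
            seed=config.seed,
            keep_fits=True,
        )
        if len(ks) >= 3:
            ev = evanno_delta_k(lnpd_runs)
            ev.table.round(4).to_csv(out / "evanno.tsv", sep="\t")
            best_k = ev.best_k
        else:
            best_k = max(lnpd_runs, key=lambda k: float(np.mean(lnpd_runs[k])))
        manifest["best_k"] = best_k
        fit = fits[(best_k, 0)]
        with open(out / "q_matrix.tsv", "w", encoding="utf-8") as fh:
            fh.write(
                "accession\tpopulation\t" + "\t".join(f"Q{k + 1}" for k in range(best_k)) + "\n"
            )
            for (acc, pop), qrow in zip(gm.accessions, fit.Q):
                fh.write(f"{acc}\t{pop}\t" + "\t".join(f"{q:.4f}" for q in qrow) + "\n")
        labels, counts = assign_groups(fit, config.q_thresholds)
        manifest["q_threshold_counts"] = {str(t): c for t, c in counts.items()}

    stage("structure", _structure)

    def _fingerprint():
        core, report = select_core_markers(gm)
        report.to_csv(out / "core_markers.tsv", sep="\t", index=False)
        panel_loci = core if core else list(gm.loci)
        sub = gm.subset_loci(panel_loci)
        codebook = build_codebook(sub)
        codebook.to_tsv(out / "codebook.tsv")
        records = encode_fingerprints(sub, codebook)
        records_to_tsv(records, out / "fingerprints.tsv")
        dups = find_duplicates(gm, config.duplicate_max_loci)
        with open(out / "duplicates.tsv", "w", encoding="utf-8") as fh:
            fh.write("accession_a\taccession_b\tn_differing\tdiffering_loci\n")
            for a, b, diff in dups:
                fh.write(f"{a}\t{b}\t{len(diff)}\t{','.join(diff)}\n")
        manifest["core_markers"] = core
        manifest["n_duplicate_pairs"] = len(dups)

    stage("fingerprint", _fingerprint)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
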