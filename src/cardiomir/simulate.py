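"""Seeded generators for every input the pipeline consumes.

The generator emulates the mimic-transfection experiment the pipeline was
built for: neonatal rat cardiomyocytes transfected with a control mimic
(cel-miR-67) or one of the three miR-106b~25 cluster members, sequenced at
gene level.  Planted targets of each miRNA have their expected counts
divided by a known repression factor in that miRNA's column only, and the
ground truth (planted sets, effect sizes, homology pairs, compartment
membership) is returned alongside so downstream recovery can be scored.

Counts are negative-binomial around per-gene baselines with variance
mu + dispersion * mu^2 (the standard RNA-seq overdispersion assumption).
Knowledge bases (seed-family predictions in mouse identifiers, mouse<->rat
homology groups, a scored interaction scaffold, GO-style gene sets) are
drawn so that the full targetome chain -- best-score reduction, homology
translation, DE intersection -- is exercised nontrivially.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cardiomir import CONTROL_MIMIC, MIRNAS
from cardiomir.exceptions import ConfigurationError, InputError
from cardiomir.expression import GeneExpressionMatrix


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment, with one master seed.

    Identical config (seed included) always reproduces bit-identical
    outputs.  Defaults describe the emulated experiment: 3 treatment
    mimics plus control, two million mapped reads per sample, 5% of genes
    planted as targets per miRNA with two-fold repression, and GO-style
    compartments sized like the curated catalogues (212 cell-division,
    345 actin-cytoskeleton, 143 oxidative-stress, 19 canonical-Hippo,
    21 non-canonical-Hippo genes, scaled down when the universe is small).
    """

    seed: int = 0
    n_genes: int = 2000
    mirna_labels: tuple[str, ...] = MIRNAS
    control_label: str = CONTROL_MIMIC
    frac_targets_per_mirna: float = 0.05
    overlap_frac: float = 0.5  # targets shared between the first two miRNAs
    repression_fc: float = 2.0  # applied as division of the planted mean
    library_size: float = 2e6
    nb_dispersion: float = 0.05  # variance = mu + dispersion * mu^2
    gene_length_range: tuple[int, int] = (200, 10_000)
    baseline_log10_mean: float = 0.0  # lognormal molar-abundance baseline
    baseline_log10_sd: float = 0.5
    homology_dropout: float = 0.05
    many_to_one_frac: float = 0.05
    decoy_frac: float = 1.0  # decoy predictions per planted target
    sites_max: int = 3  # prediction rows per (family, gene) pair
    ppi_n_edges: int = 4000
    ppi_score_distribution: tuple[int, int] = (150, 999)  # uniform ints
    go_set_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "cell_division": 212,
            "actin_cytoskeleton": 345,
            "oxidative_stress": 143,
            "hippo_canonical": 19,
            "hippo_noncanonical": 21,
        }
    )
    compartment_target_bias: float = 0.5  # cell_division share drawn from planted

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_labels)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        if not 0 < self.frac_targets_per_mirna < 1:
            raise ConfigurationError("frac_targets_per_mirna must lie in (0, 1)")
        if self.frac_targets_per_mirna * self.n_genes < 1:
            raise ConfigurationError("frac_targets_per_mirna * n_genes must be >= 1")
        if self.repression_fc < 1:
            raise ConfigurationError("repression_fc must be >= 1 (applied as division)")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if not 0 <= self.homology_dropout < 1:
            raise ConfigurationError("homology_dropout must lie in [0, 1)")
        if self.decoy_frac < 0:
            raise ConfigurationError("decoy_frac must be non-negative")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ConfigurationError("gene_length_range must be a positive interval")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mirna_labels"] = list(self.mirna_labels)
        d["gene_length_range"] = list(self.gene_length_range)
        d["ppi_score_distribution"] = list(self.ppi_score_distribution)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("mirna_labels", "gene_length_range", "ppi_score_distribution"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    planted_targets: dict[str, set]  # miRNA -> rat gene set
    effect_sizes: dict[tuple[str, str], float]  # (miRNA, gene) -> fold repression
    homology_pairs: list[tuple[str, str]] = field(default_factory=list)  # (mouse, rat)
    compartment_membership: dict[str, set] = field(default_factory=dict)
    expected_counts: pd.DataFrame | None = None  # NB means, genes x conditions

    def to_json(self, path) -> None:
        payload = {
            "planted_targets": {m: sorted(s) for m, s in self.planted_targets.items()},
            "effect_sizes": {f"{m}\t{g}": v for (m, g), v in self.effect_sizes.items()},
            "homology_pairs": sorted(self.homology_pairs),
            "compartment_membership": {
                c: sorted(s) for c, s in self.compartment_membership.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        effect = {}
        for key, v in payload["effect_sizes"].items():
            m, g = key.split("\t")
            effect[(m, g)] = v
        return cls(
            planted_targets={m: set(s) for m, s in payload["planted_targets"].items()},
            effect_sizes=effect,
            homology_pairs=[tuple(p) for p in payload["homology_pairs"]],
            compartment_membership={
                c: set(s) for c, s in payload["compartment_membership"].items()
            },
        )


def _rat_id(i: int) -> str:
    return f"Rgene{i:05d}"


def _mouse_id(i: int) -> str:
    return f"Mgene{i:05d}"


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible substreams per generator stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_transfection_counts(
    config: SimulationConfig,
) -> tuple[GeneExpressionMatrix, SyntheticTruth]:
    """Gene-level count matrix (control + one column per miRNA) plus truth.

    Per-gene molar abundances are lognormal; expected counts split the
    library proportionally to abundance x length (reads scale with
    transcript footprint), so RPKM recovers the abundance scale.  Planted
    targets have their expected count divided by ``repression_fc`` in their
    miRNA's column only.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_genes
    genes = [_rat_id(i) for i in range(n)]
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    abundance = 10.0 ** rng.normal(config.baseline_log10_mean, config.baseline_log10_sd, n)

    n_targets = int(round(config.frac_targets_per_mirna * n))
    planted: dict[str, set] = {}
    labels = list(config.mirna_labels)
    first = rng.choice(n, size=n_targets, replace=False)
    planted[labels[0]] = {genes[i] for i in first}
    for j, mirna in enumerate(labels[1:], start=1):
        if j == 1 and len(labels) >= 2:
            n_shared = int(round(config.overlap_frac * n_targets))
            shared = rng.choice(first, size=n_shared, replace=False)
            pool = np.setdiff1d(np.arange(n), first)
            fresh = rng.choice(pool, size=n_targets - n_shared, replace=False)
            idx = np.concatenate([shared, fresh])
        else:
            idx = rng.choice(n, size=n_targets, replace=False)
        planted[mirna] = {genes[i] for i in idx}

    effect_sizes = {
        (m, g): float(config.repression_fc) for m, gs in planted.items() for g in gs
    }

    gene_pos = {g: i for i, g in enumerate(genes)}
    weight_base = abundance * lengths / 1e3
    conditions = [config.control_label] + labels
    mu = np.empty((n, len(conditions)))
    for c, cond in enumerate(conditions):
        w = weight_base.copy()
        if cond in planted:
            for g in planted[cond]:
                w[gene_pos[g]] /= config.repression_fc
        mu[:, c] = config.library_size * w / w.sum()

    if config.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=conditions)
    matrix = GeneExpressionMatrix(
        counts=counts_df,
        lengths_bp=pd.Series(lengths, index=counts_df.index, name="length_bp"),
        control=config.control_label,
    )
    truth = SyntheticTruth(
        planted_targets=planted,
        effect_sizes=effect_sizes,
        expected_counts=pd.DataFrame(mu, index=counts_df.index, columns=conditions),
    )
    return matrix, truth


def _family_of(mirna: str) -> str:
    return f"{mirna}-family"


def simulate_knowledge_bases(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, set]]:
    """Prediction table, homology table, scored edge list and gene sets.

    * homology: rat gene i <-> mouse gene i in homology group HG<i>;
      a ``homology_dropout`` fraction of non-planted genes lacks a mouse
      partner, and a ``many_to_one_frac`` fraction of groups carries a
      second mouse paralog (exercising many-to-one collapse).  Planted
      targets always keep their partner so the prediction postcondition
      (all planted targets present, in mouse identifiers) holds for any
      dropout.
    * predictions: per miRNA seed family, all planted targets plus
      ``decoy_frac`` x as many decoys, 1..sites_max site rows each with
      context-style scores (more negative = stronger) drawn from one
      distribution for targets and decoys alike.
    * interaction scaffold: ``ppi_n_edges`` distinct rat-protein pairs
      with integer combined scores uniform on ``ppi_score_distribution``.
    * gene sets: compartment catalogues realizing ``go_set_sizes``; the
      cell_division compartment draws ``compartment_target_bias`` of its
      members from the planted union (the enrichment signal).
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_genes
    rat_genes = [_rat_id(i) for i in range(n)]
    planted_union: set[str] = set()
    for s in truth.planted_targets.values():
        planted_union |= s

    # --- homology -----------------------------------------------------------
    rat_to_mouse: dict[str, str] = {}
    rows = []
    extra_paralog = 0
    for i, rat in enumerate(rat_genes):
        droppable = rat not in planted_union
        if droppable and rng.random() < config.homology_dropout:
            continue
        mouse = _mouse_id(i)
        group = f"HG{i:05d}"
        rows.append((group, "rat", rat))
        rows.append((group, "mouse", mouse))
        rat_to_mouse[rat] = mouse
        if rng.random() < config.many_to_one_frac:
            extra_paralog += 1
            rows.append((group, "mouse", f"{mouse}b"))
    homology = pd.DataFrame(rows, columns=["group_id", "species", "gene_id"])
    # resolve group -> rat for pair bookkeeping
    group_rat = {g: gid for g, sp, gid in rows if sp == "rat"}
    truth.homology_pairs = [
        (gid, group_rat[g]) for g, sp, gid in rows if sp == "mouse" and g in group_rat
    ]

    # --- seed-family predictions -------------------------------------------
    pred_rows = []
    mapped_rat = set(rat_to_mouse)
    for mirna in config.mirna_labels:
        fam = _family_of(mirna)
        targets = sorted(truth.planted_targets[mirna])
        n_decoys = int(round(config.decoy_frac * len(targets)))
        decoy_pool = sorted(mapped_rat - truth.planted_targets[mirna])
        decoys = list(rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)), replace=False))
        for rat in targets + decoys:
            mouse = rat_to_mouse[rat]
            n_sites = int(rng.integers(1, config.sites_max + 1))
            scores = -rng.uniform(0.05, 0.6, size=n_sites)
            for s in scores:
                pred_rows.append((mirna, fam, mouse, round(float(s), 3)))
    predictions = pd.DataFrame(pred_rows, columns=["mirna", "family", "mouse_gene", "score"])

    # --- scored interaction scaffold ---------------------------------------
    max_edges = n * (n - 1) // 2
    if config.ppi_n_edges > max_edges:
        raise ConfigurationError("ppi_n_edges exceeds the number of distinct pairs")
    lo, hi = config.ppi_score_distribution
    seen: set[tuple[int, int]] = set()
    edge_rows = []
    while len(edge_rows) < config.ppi_n_edges:
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        score = int(rng.integers(lo, hi + 1))
        edge_rows.append((rat_genes[key[0]], rat_genes[key[1]], score))
    ppi = pd.DataFrame(edge_rows, columns=["protein1", "protein2", "combined_score"])

    # --- GO-style compartment catalogues -----------------------------------
    compartments: dict[str, set] = {}
    planted_sorted = sorted(planted_union)
    for label in sorted(config.go_set_sizes):
        size = min(config.go_set_sizes[label], n)
        if label == "cell_division" and planted_sorted:
            n_bias = min(int(round(config.compartment_target_bias * size)), len(planted_sorted))
            biased = list(rng.choice(planted_sorted, size=n_bias, replace=False))
            rest_pool = sorted(set(rat_genes) - set(biased))
            rest = list(rng.choice(rest_pool, size=size - n_bias, replace=False))
            compartments[label] = set(biased) | set(rest)
        else:
            compartments[label] = set(rng.choice(rat_genes, size=size, replace=False))
    truth.compartment_membership = compartments

    return predictions, homology, ppi, compartments


def simulate_echo_cohort(
    group_means: pd.DataFrame,
    group_sems: pd.DataFrame,
    n_per_group,
    seed: int,
) -> pd.DataFrame:
    """Per-animal echo records drawn around published group summaries.

    Values are normal with sd = SEM * sqrt(n) (the per-animal spread the
    printed SEM implies).  ``n_per_group`` is an int or a per-group Series.
    Used to demonstrate the mean-of-formula vs formula-on-means gap, not to
    model echo physics.
    """
    rng = np.random.default_rng(seed)
    if (group_means <= 0).any().any():
        raise InputError("group means must be strictly positive")
    if (group_sems < 0).any().any():
        raise InputError("SEMs must be non-negative")
    if {"LVIDd", "LVIDs"} <= set(group_means.columns):
        bad = group_means["LVIDs"] >= group_means["LVIDd"]
        if bad.any():
            raise InputError(f"LVIDs mean >= LVIDd mean for groups {list(group_means.index[bad])}")
    rows = []
    for group in group_means.index:
        n = int(n_per_group[group]) if hasattr(n_per_group, "__getitem__") and not isinstance(
            n_per_group, (int, np.integer)
        ) else int(n_per_group)
        if n <= 0:
            raise InputError("n_per_group must be positive")
        for _ in range(n):
            row = {"group": group}
            for measure in group_means.columns:
                mean = group_means.loc[group, measure]
                sem = group_sems.loc[group, measure]
                sd = sem * np.sqrt(n)
                value = rng.normal(mean, sd)
                row[measure] = max(value, 1e-3)  # dimensions are physical, keep positive
            rows.append(row)
    return pd.DataFrame(rows)


def write_inputs(
    config: SimulationConfig,
    outdir,
    echo_study: str = "ko_tac",
) -> dict[str, str]:
    """Run both generators and write every pipeline input under ``outdir``.

    Returns a name -> path map (counts TSV, predictions TSV, homology TSV,
    edge TSV, compartments GMT, truth JSON, echo CSV).
    """
    from pathlib import Path

    from cardiomir import io as cio
    from cardiomir.cohorts import cohort_means, cohort_ns, cohort_sems

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_transfection_counts(config)
    predictions, homology, ppi, compartments = simulate_knowledge_bases(config, truth)

    paths = {
        "counts": outdir / "counts.tsv",
        "predictions": outdir / "predictions.tsv",
        "homology": outdir / "homology.tsv",
        "ppi_edges": outdir / "ppi_edges.tsv",
        "compartments": outdir / "compartments.gmt",
        "truth": outdir / "truth.json",
        "echo": outdir / "echo_cohort.csv",
    }
    matrix.to_tsv(paths["counts"])
    predictions.to_csv(paths["predictions"], sep="\t", index=False)
    homology.to_csv(paths["homology"], sep="\t", index=False)
    ppi.to_csv(paths["ppi_edges"], sep="\t", index=False)
    cio.write_gmt(compartments, paths["compartments"])
    truth.to_json(paths["truth"])

    means = cohort_means(echo_study).drop(columns=["LV_mass", "LV_mass_BW", "EF", "FS", "EA"], errors="ignore")
    sems = cohort_sems(echo_study).drop(columns=["LV_mass", "LV_mass_BW", "EF", "FS", "EA"], errors="ignore")
    cohort = simulate_echo_cohort(means, sems, cohort_ns(echo_study), seed=config.seed)
    cohort.to_csv(paths["echo"], index=False)
    return {k: str(v) for k, v in paths.items()}
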