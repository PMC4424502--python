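"""Study-shaped synthetic data: expression matrices, catalogs, ground truth.

The generator emulates a two-platform reperfusion time-course experiment:
log2-scale mRNA expression at {0, 24, 168} h and miRNA expression at
{0, 2, 24, 48, 168} h, each with sham and injured groups of six replicates
per time point.  A configurable number of (miR, TF, gene) loops is planted:
all three members of a loop share a unit-peak piecewise-linear response
curve r(t) scaled by a log2 effect size and added to the injured group only
(the miR with a configurable coupling sign).  Decoy entities carry noise
only, and decoy interaction pairs connect exclusively non-planted entities,
so null edges are independent by construction.

Everything is reproducible from the seed, and :func:`evaluate_recovery`
scores a reported loop set against the planted truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_processing import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SyntheticStudy",
    "response_curve",
    "simulate_study",
    "evaluate_recovery",
    "save_study",
]

DEFAULT_MRNA_TIMEPOINTS = (0.0, 24.0, 168.0)
DEFAULT_MIRNA_TIMEPOINTS = (0.0, 2.0, 24.0, 48.0, 168.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Effects are in log2 units; the default effect of 2.0 corresponds to a
    four-fold change at the response peak, comfortably above the two-fold
    differential-expression cutoff.  ``peak_time_h`` places the response
    maximum (24 h by default, where the real injury response is largest);
    ``late_level`` is the fraction of the peak remaining at the last time
    point (0.75, matching a late response about three quarters of the
    early one).  Setting ``peak_time_h`` to the final time point yields a
    monotone ramp, for which straight-line imputation of the mRNA platform
    is exact.
    """

    n_mirs: int = 30
    n_tfs: int = 6
    n_genes: int = 80
    n_planted_loops: int = 10
    n_decoy_pairs_per_class: int = 40
    mrna_timepoints: tuple[float, ...] = DEFAULT_MRNA_TIMEPOINTS
    mirna_timepoints: tuple[float, ...] = DEFAULT_MIRNA_TIMEPOINTS
    replicates_per_group: int = 6
    de_log2_effect: float = 2.0
    noise_sd: float = 0.3
    coupling_sign: int = 1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    peak_time_h: float = 24.0
    late_level: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirs", "n_tfs", "n_genes", "n_planted_loops",
                     "n_decoy_pairs_per_class"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates_per_group <= 0:
            raise ValueError("replicates_per_group must be positive")
        if self.coupling_sign not in (1, -1):
            raise ValueError("coupling_sign must be +1 or -1")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_planted_loops > 0:
            if self.n_planted_loops > min(self.n_mirs, self.n_genes) or self.n_tfs < 1:
                raise ValueError(
                    "n_planted_loops requires at least as many miRs/genes and >= 1 TF"
                )


@dataclass
class TruthTable:
    """Planted loops and the per-time-point expression changes they imply."""

    loops: pd.DataFrame       # mir, tf, gene, coupling_sign, curve_id
    de_entities: pd.DataFrame  # entity_id, class, time_h, true_log2fc

    @property
    def loop_keys(self) -> set[tuple[str, str, str]]:
        return set(zip(self.loops["mir"], self.loops["tf"], self.loops["gene"]))

    @property
    def planted_entities(self) -> set[str]:
        return (
            set(self.loops["mir"]) | set(self.loops["tf"]) | set(self.loops["gene"])
        )


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    catalogs: dict[str, pd.DataFrame]
    truth: TruthTable

    @property
    def tf_ids(self) -> list[str]:
        return [e for e in self.mrna.entity_ids if e.startswith("TF-")]


def response_curve(times, peak_time_h: float, late_level: float) -> np.ndarray:
    """Unit-peak piecewise-linear curve: 0 at t=0, 1 at the peak, late_level at the end."""
    t = np.asarray(times, dtype=float)
    t_end = t.max()
    if peak_time_h >= t_end:
        knots_t, knots_r = [0.0, t_end], [0.0, 1.0]
    else:
        knots_t, knots_r = [0.0, peak_time_h, t_end], [0.0, 1.0, late_level]
    return np.interp(t, knots_t, knots_r)


def _sample_table(platform: str, timepoints, reps: int) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{platform}_{grp}_t{int(t)}_r{r}",
            "group": grp,
            "time_h": float(t),
            "replicate": r,
        }
        for grp in ("sham", "injured")
        for t in timepoints
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(rows)


def _matrix(
    rng: np.random.Generator,
    entities: list[str],
    signs: dict[str, int],
    timepoints,
    cfg: SimulationConfig,
    platform: str,
) -> ExpressionMatrix:
    samples = _sample_table(platform, timepoints, cfg.replicates_per_group)
    curve = dict(
        zip(timepoints, response_curve(timepoints, cfg.peak_time_h, cfg.late_level))
    )
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(entities))
    vals = np.tile(baseline[:, None], (1, len(samples)))
    sign_vec = np.array([signs.get(e, 0) for e in entities], dtype=float)
    for j, rec in enumerate(samples.itertuples(index=False)):
        if rec.group == "injured":
            vals[:, j] += sign_vec * cfg.de_log2_effect * curve[rec.time_h]
    if cfg.noise_sd > 0:
        vals += rng.normal(0.0, cfg.noise_sd, size=vals.shape)
    values = pd.DataFrame(vals, index=entities, columns=samples["sample_id"])
    return ExpressionMatrix(
        values=values, samples=samples, entity_class="miR" if platform == "mirna" else "mRNA"
    )


def _decoy_pairs(
    rng: np.random.Generator, sources: list[str], targets: list[str], k: int, label: str
) -> pd.DataFrame:
    combos = [(s, t) for s in sources for t in targets if s != t]
    if k > len(combos):
        raise ValueError(
            f"cannot draw {k} decoy {label} pairs from {len(combos)} combinations"
        )
    idx = rng.choice(len(combos), size=k, replace=False)
    rows = [combos[i] for i in sorted(idx)]
    return pd.DataFrame(rows, columns=["source_id", "target_id"]).assign(
        provenance=lambda d: [frozenset(["decoy"])] * len(d)
    )


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate matrices, interaction catalogs and the planted-loop truth table."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mirs = [f"miR-{i:03d}" for i in range(1, cfg.n_mirs + 1)]
    tfs = [f"TF-{i:02d}" for i in range(1, cfg.n_tfs + 1)]
    genes = [f"gene-{i:04d}" for i in range(1, cfg.n_genes + 1)]
    all_ids = mirs + tfs + genes
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate entity ids generated")

    # planted loops: distinct miRs and genes; TFs reused cyclically so that,
    # as in real networks, a few TFs participate in many loops
    p_mirs = sorted(rng.choice(mirs, size=cfg.n_planted_loops, replace=False))
    p_genes = sorted(rng.choice(genes, size=cfg.n_planted_loops, replace=False))
    # leave at least one TF unplanted when decoy pairs are requested
    tf_cap = max(1, cfg.n_tfs - 1) if cfg.n_decoy_pairs_per_class > 0 else cfg.n_tfs
    n_tf_used = min(tf_cap, max(1, cfg.n_planted_loops // 3)) if cfg.n_planted_loops else 0
    p_tfs_pool = sorted(rng.choice(tfs, size=n_tf_used, replace=False)) if n_tf_used else []
    curve_id = f"peak{cfg.peak_time_h:g}"
    loops = pd.DataFrame(
        {
            "mir": p_mirs,
            "tf": [p_tfs_pool[i % len(p_tfs_pool)] for i in range(cfg.n_planted_loops)],
            "gene": p_genes,
            "coupling_sign": cfg.coupling_sign,
            "curve_id": curve_id,
        }
    )

    signs: dict[str, int] = {}
    for rec in loops.itertuples(index=False):
        signs[rec.mir] = cfg.coupling_sign
        signs[rec.tf] = 1
        signs[rec.gene] = 1

    mrna = _matrix(rng, tfs + genes, signs, cfg.mrna_timepoints, cfg, "mrna")
    mirna = _matrix(rng, mirs, signs, cfg.mirna_timepoints, cfg, "mirna")

    planted = set(signs)
    d_mirs = [m for m in mirs if m not in planted]
    d_tfs = [f for f in tfs if f not in planted]
    d_genes = [g for g in genes if g not in planted]
    prov = [frozenset(["planted"])] * len(loops)
    catalogs = {
        "mir_tf": pd.concat(
            [
                loops[["mir", "tf"]].set_axis(["source_id", "target_id"], axis=1)
                .assign(provenance=prov),
                _decoy_pairs(rng, d_mirs, d_tfs, cfg.n_decoy_pairs_per_class, "miR->TF"),
            ],
            ignore_index=True,
        ),
        "mir_gene": pd.concat(
            [
                loops[["mir", "gene"]].set_axis(["source_id", "target_id"], axis=1)
                .assign(provenance=prov),
                _decoy_pairs(rng, d_mirs, d_genes, cfg.n_decoy_pairs_per_class, "miR->gene"),
            ],
            ignore_index=True,
        ),
        "tf_gene": pd.concat(
            [
                loops[["tf", "gene"]].set_axis(["source_id", "target_id"], axis=1)
                .assign(provenance=prov),
                _decoy_pairs(rng, d_tfs, d_genes, cfg.n_decoy_pairs_per_class, "TF->gene"),
            ],
            ignore_index=True,
        ),
    }
    # duplicates can arise when a planted pair recurs; collapse them
    for key, df in catalogs.items():
        catalogs[key] = (
            df.groupby(["source_id", "target_id"], sort=True)["provenance"]
            .agg(lambda s: frozenset().union(*s))
            .reset_index()
        )

    grid = sorted(set(cfg.mrna_timepoints) | set(cfg.mirna_timepoints))
    curve = response_curve(grid, cfg.peak_time_h, cfg.late_level)
    de_rows = []
    for ent in sorted(planted):
        cls = "miR" if ent.startswith("miR-") else ("TF" if ent.startswith("TF-") else "mRNA")
        for t, r in zip(grid, curve):
            de_rows.append(
                {
                    "entity_id": ent,
                    "class": cls,
                    "time_h": t,
                    "true_log2fc": signs[ent] * cfg.de_log2_effect * r,
                }
            )
    truth = TruthTable(
        loops=loops,
        de_entities=pd.DataFrame(
            de_rows, columns=["entity_id", "class", "time_h", "true_log2fc"]
        ),
    )
    return SyntheticStudy(config=cfg, mrna=mrna, mirna=mirna, catalogs=catalogs, truth=truth)


def evaluate_recovery(reported_loops, truth: TruthTable) -> tuple[float, float]:
    """Sensitivity and false-discovery fraction of a reported loop set.

    ``reported_loops`` may hold (mir, tf, gene) tuples or objects with a
    ``key`` attribute.  Sensitivity = recovered planted / planted;
    false-discovery fraction = reported non-planted / reported (0 with a
    warning when nothing was reported).
    """
    planted = truth.loop_keys
    if not planted:
        raise ValueError("truth table contains no planted loops")
    keys = {tuple(l.key) if hasattr(l, "key") else tuple(l) for l in reported_loops}
    if not keys:
        warnings.warn("no loops reported; sensitivity and FDR set to 0")
        return 0.0, 0.0
    sens = len(keys & planted) / len(planted)
    fdf = len(keys - planted) / len(keys)
    return sens, fdf


def save_study(study: SyntheticStudy, directory) -> None:
    """Write the study as plain TSV/JSON files (seed recorded in header comments)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    header = f"# seed: {study.config.seed}\n"
    for name, mat in (("mrna", study.mrna), ("mirna", study.mirna)):
        with open(d / f"{name}.tsv", "w") as fh:
            fh.write(header)
            fh.write(mat.values.rename_axis("entity_id").to_csv(sep="\t"))
        mat.samples.to_csv(d / f"{name}_samples.tsv", sep="\t", index=False)
    for name, df in study.catalogs.items():
        rows = [
            {"source_id": r.source_id, "target_id": r.target_id, "catalog": c}
            for r in df.itertuples(index=False)
            for c in sorted(r.provenance)
        ]
        pd.DataFrame(rows).to_csv(d / f"pairs_{name}.tsv", sep="\t", index=False)
    study.truth.loops.to_csv(d / "truth_loops.tsv", sep="\t", index=False)
    study.truth.de_entities.to_csv(d / "truth_de.tsv", sep="\t", index=False)
    with open(d / "tf_ids.txt", "w") as fh:
        fh.write("\n".join(study.tf_ids) + "\n")
    with open(d / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=2, default=list)
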