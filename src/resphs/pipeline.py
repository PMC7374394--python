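"""End-to-end runs: configuration, commands, and a surrogate objective.

The pipeline ties the simulator, the CNN objective and the Harmony Search
engine together behind four commands — simulate, optimize, grid, evaluate —
each usable as a function or through the CLI.  A single master seed derives
every module's random stream deterministically, so a run is reproducible
from its archived config alone.

The surrogate objective is a cheap stand-in for the CNN: a smooth unimodal
score with its unique maximum planted at a known hyperparameter vector.  It
makes optimizer behaviour testable against brute-force enumeration without
any training.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .space import (
    HPVector,
    HyperparameterSpace,
    cardinality,
    enumerate_space,
    validate_hp,
)
from .hs import Harmony, OptimizationTrace, run_hs, sample_hs_params, write_trace, write_trajectory
from .signals import (
    PatternType,
    RespirationDataset,
    generate_dataset,
    save_dataset,
    split_dataset,
)
from .cnn import EvaluationResult, TrainingConfig, build_model, evaluate_model, make_objective, train_model

__all__ = [
    "RunConfig",
    "SurrogateObjective",
    "surrogate_score",
    "derive_rngs",
    "cmd_simulate",
    "cmd_optimize",
    "cmd_grid_baseline",
    "cmd_evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one run.

    Defaults are desk-scale: the simulation follows the 10-subject,
    50-pieces-per-type, 1500-pool/1000-test protocol, while the search space
    and training budget are deliberately shrunk so a full optimize run fits
    on a laptop CPU; the full published space remains reachable through the
    space block.
    """

    seed: int = 0
    out_dir: str = "runs"
    # simulation block
    n_subjects: int = 10
    pieces_per_type: int = 50
    fs: float = 20.0
    duration: float = 10.0
    noise: float = 0.05
    n_train_pool: int = 1500
    val_fraction: float = 0.2
    # search-space block (desk-scale defaults; full space: 3..81/16..1024/256..4096, cld 3)
    space: HyperparameterSpace = field(
        default_factory=lambda: HyperparameterSpace(
            cld=2, ks_min=3, ks_max=15, kc_min=4, kc_max=16, dlnc_min=8, dlnc_max=64
        )
    )
    # HS block: None means "sample from the recommended grid"
    hmcr: Optional[float] = None
    par: Optional[float] = None
    mpap: Optional[int] = None
    hms: int = 20
    max_iterations: int = 60
    k: int = 200
    # training block
    training: TrainingConfig = field(default_factory=TrainingConfig)
    resplit_per_call: bool = False
    grid_budget: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        space = raw.pop("space", None)
        training = raw.pop("training", None)
        cfg = cls(**raw)
        if space is not None:
            cfg.space = HyperparameterSpace(**space)
        if training is not None:
            cfg.training = TrainingConfig(**training)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def derive_rngs(master_seed: int, n: int = 4) -> list[np.random.Generator]:
    """Derive independent module streams (simulate, split, search, train)
    from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


@dataclass(frozen=True)
class SurrogateObjective:
    """Unimodal score with a planted optimum, for optimizer verification.

    ``score = 100 * exp(-sum(((x - target) / scale)^2))`` with per-axis
    scales equal to the axis widths; 100 is attained exactly and only at the
    target, and the score strictly decreases as any coordinate moves away.
    """

    target: HPVector
    space: HyperparameterSpace

    def scales(self) -> np.ndarray:
        widths = []
        for axis, count in (("KS", self.space.cld), ("KC", self.space.cld), ("DLNC", 2)):
            lo, hi = self.space.axis_bounds(axis)
            widths.extend([max(hi - lo, 1)] * count)
        return np.array(widths, dtype=float)

    def __call__(self, hp: HPVector) -> float:
        return surrogate_score(hp, self)


def surrogate_score(hp: HPVector, surrogate: SurrogateObjective) -> float:
    """Evaluate the surrogate at one candidate (percent in (0, 100])."""
    x = np.array(hp.as_tuple(), dtype=float)
    t = np.array(surrogate.target.as_tuple(), dtype=float)
    z = (x - t) / surrogate.scales()
    return float(100.0 * np.exp(-np.sum(z**2)))


def _prepare_dataset(config: RunConfig, rng_sim, rng_split) -> RespirationDataset:
    ds = generate_dataset(
        config.n_subjects, config.pieces_per_type,
        fs=config.fs, duration=config.duration, rng=rng_sim, noise=config.noise,
    )
    split_dataset(ds, config.n_train_pool, config.val_fraction, rng_split)
    return ds


def cmd_simulate(config: RunConfig, out_dir=None) -> RespirationDataset:
    """Generate the dataset, split it, and write it with checksums."""
    rng_sim, rng_split, _, _ = derive_rngs(config.seed)
    ds = _prepare_dataset(config, rng_sim, rng_split)
    out = Path(out_dir if out_dir is not None else config.out_dir) / "dataset"
    save_dataset(ds, out)
    counts = ds.class_counts()
    sizes = {k: len(getattr(ds.splits, k)) for k in ("train", "val", "test")}
    print(f"wrote {len(ds)} pieces to {out}")
    print(f"class counts: {counts}")
    print(f"split sizes: {sizes}")
    return ds


def _build_objective(config: RunConfig, surrogate: Optional[SurrogateObjective],
                     dataset: Optional[RespirationDataset]):
    if surrogate is not None:
        return surrogate, None
    rng_sim, rng_split, _, rng_train = derive_rngs(config.seed)
    ds = dataset if dataset is not None else _prepare_dataset(config, rng_sim, rng_split)
    if ds.splits is None:
        split_dataset(ds, config.n_train_pool, config.val_fraction, rng_split)
    objective = make_objective(
        ds, config.training, rng_train,
        resplit_per_call=config.resplit_per_call, val_fraction=config.val_fraction,
    )
    return objective, ds


def cmd_optimize(
    config: RunConfig,
    *,
    surrogate: Optional[SurrogateObjective] = None,
    dataset: Optional[RespirationDataset] = None,
    out_dir=None,
) -> tuple[Harmony, OptimizationTrace]:
    """Run Harmony Search on the CNN objective (or a surrogate) and write
    the best-update trajectory, the per-iteration trace, and a summary."""
    _, _, rng_search, _ = derive_rngs(config.seed)
    params = sample_hs_params(
        rng_search, hmcr=config.hmcr, par=config.par, mpap=config.mpap,
        hms=config.hms, max_iterations=config.max_iterations, k=config.k,
        seed=config.seed,
    )
    objective, _ds = _build_objective(config, surrogate, dataset)
    best, trace = run_hs(objective, config.space, params, rng_search)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trajectory(trace, out / "trajectory.tsv", config.space.cld)
    write_trace(trace, out / "trace.tsv")
    config.to_yaml(out / "config.yaml")
    summary = {
        "best_hp": {"ks": list(best.hp.ks), "kc": list(best.hp.kc), "dlnc": list(best.hp.dlnc)},
        "best_rate": best.r,
        "termination": trace.termination,
        "iterations": len(trace.records),
        "evaluations": trace.n_evaluations,
        "hs_params": {"hmcr": params.hmcr, "par": params.par, "mpap": params.mpap,
                      "hms": params.hms, "k": params.k},
        "space_cardinality": str(cardinality(config.space)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"best rate {best.r:.1f}% after {len(trace.records)} iterations "
          f"({trace.termination}); hp={best.hp.as_tuple()}")
    return best, trace


def cmd_grid_baseline(
    config: RunConfig,
    grid: dict[str, list[int]],
    *,
    surrogate: Optional[SurrogateObjective] = None,
    dataset: Optional[RespirationDataset] = None,
) -> tuple[Harmony, int]:
    """Exhaustive grid baseline over explicit per-axis value lists.

    ``grid`` maps ``ks``/``kc``/``dlnc`` to candidate value lists; every
    Cartesian combination (per-layer axes expanded to all layer tuples) is
    evaluated.  Refuses with the count printed when the product exceeds the
    configured budget.
    """
    for axis_key, axis_name in (("ks", "KS"), ("kc", "KC"), ("dlnc", "DLNC")):
        lo, hi = config.space.axis_bounds(axis_name)
        for v in grid[axis_key]:
            if not lo <= v <= hi:
                raise ValueError(f"grid value {axis_key}={v} outside space bounds [{lo}, {hi}]")
    cld = config.space.cld
    n_combos = len(grid["ks"]) ** cld * len(grid["kc"]) ** cld * len(grid["dlnc"]) ** 2
    if n_combos > config.grid_budget:
        raise RuntimeError(
            f"grid of {n_combos} combinations exceeds budget {config.grid_budget}; refusing"
        )
    objective, _ = _build_objective(config, surrogate, dataset)
    best: Optional[Harmony] = None
    for ks in itertools.product(grid["ks"], repeat=cld):
        for kc in itertools.product(grid["kc"], repeat=cld):
            for dlnc in itertools.product(grid["dlnc"], repeat=2):
                hp = HPVector(ks=ks, kc=kc, dlnc=dlnc)  # type: ignore[arg-type]
                r = float(objective(hp))
                if best is None or r > best.r:
                    best = Harmony(hp=hp, r=r)
    assert best is not None
    print(f"grid best {best.r:.1f}% over {n_combos} evaluations; hp={best.hp.as_tuple()}")
    return best, n_combos


def cmd_evaluate(
    config: RunConfig,
    hp: HPVector,
    *,
    dataset: Optional[RespirationDataset] = None,
    out_dir=None,
) -> EvaluationResult:
    """Final test report for one architecture.

    Trains on the full learning pool (train + validation) and evaluates on
    the held-out test split, writing the confusion matrix and rate as
    delimited text.
    """
    verdict = validate_hp(config.space, hp)
    if not verdict:
        raise ValueError(f"hp invalid for configured space: {verdict.problems}")
    rng_sim, rng_split, _, rng_train = derive_rngs(config.seed)
    ds = dataset if dataset is not None else _prepare_dataset(config, rng_sim, rng_split)
    if ds.splits is None:
        raise ValueError("dataset has no splits; run split_dataset or cmd_simulate first")
    if len(ds.splits.test) == 0:
        raise ValueError("test split is empty")
    pool = np.concatenate([ds.splits.train, ds.splits.val])
    input_length = ds.pieces[0].samples.shape[0]
    model = build_model(hp, input_length, pool_width=config.training.pool_width)
    train_model(model, ds.signals(pool), ds.labels(pool), config.training, rng_train)
    result = evaluate_model(
        model, ds.signals(ds.splits.test), ds.labels(ds.splits.test),
        normalize=config.training.normalize,
    )
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = "\t".join(p.value for p in PatternType)
    np.savetxt(out / "confusion.tsv", result.confusion, fmt="%d", delimiter="\t",
               header=header, comments="")
    (out / "test_report.json").write_text(
        json.dumps({"rate": result.rate, "hp": list(hp.as_tuple())}, indent=2)
    )
    print(f"test recognition rate {result.rate:.1f}%")
    return result


def brute_force_argmax(space: HyperparameterSpace, objective) -> Harmony:
    """Exhaustively evaluate a small space; the oracle for optimizer tests."""
    best: Optional[Harmony] = None
    for hp in enumerate_space(space):
        r = float(objective(hp))
        if best is None or r > best.r:
            best = Harmony(hp=hp, r=r)
    assert best is not None
    return best
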