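"""End-to-end orchestration: simulate → compare → score → threshold →
review → evaluate, driven by one YAML/JSON config with a single seed.

Every stage writes its tabular output as headed CSV under the run's output
directory, and a ``manifest.json`` records the package version, the seed
and per-stage row counts.  Re-running the same config reproduces identical
outputs.  Real registers can enter the pipeline instead of synthetic ones
by giving ``inputs`` paths rather than a ``synthetic`` block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import perilink
from perilink.comparison import all_pairs, block_pairs, compare_pairs, default_specs
from perilink.evaluation import error_cells, linkage_metrics
from perilink.linkage import em_fit, em_score_many, epilink_score_many, fs_score_many, fs_weights
from perilink.presets import epilink_spec_from_table, get_preset
from perilink.records import read_records, write_records
from perilink.review import clerical_review, merge_candidates, threshold_table
from perilink.synthetic import (
    SyntheticConfig,
    TruthMap,
    generate_linked_datasets,
    missingness_preset,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("fs", "em", "epilink")

DEFAULT_CUTOFFS = {
    "fs": [0, 5, 10, 15, 20, 25, 30],
    "em": [0, 5, 10, 15, 20, 25, 30],
    "epilink": [0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95],
}
DEFAULT_REVIEW_CUTOFF = {"fs": 5.0, "em": 5.0, "epilink": 0.55}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "perilink_run"
    synthetic: dict | None = None
    inputs: dict | None = None           # {"cohort": path, "episodes": path, "truth": path?}
    preset: str = "best_guess"
    fields: list | None = None
    blocking_key: str | None = "date_of_birth"
    missing_policy: str = "compare_all"
    algorithms: list = field(default_factory=lambda: list(ALGORITHMS))
    em_tol: float = 1e-6
    em_max_iter: int = 100
    cutoffs: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_CUTOFFS.items()})
    review_cutoff: dict = field(default_factory=lambda: dict(DEFAULT_REVIEW_CUTOFF))
    review_mode: str = "oracle"          # oracle | interactive | none
    review_max_rounds: int = 25

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("at least one algorithm must be selected")
        bad = set(self.algorithms) - set(ALGORITHMS)
        if bad:
            raise ValueError(f"unknown algorithm(s): {sorted(bad)}")
        get_preset(self.preset)  # raises on unknown preset
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config needs either a synthetic block or input paths")
        if self.review_mode not in ("oracle", "interactive", "none"):
            raise ValueError(f"unknown review_mode {self.review_mode!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls(**data)


def _build_synthetic(cfg: RunConfig):
    spec = dict(cfg.synthetic or {})
    if isinstance(spec.get("missingness_rates"), str):
        spec["missingness_rates"] = missingness_preset(spec["missingness_rates"])
    if "probability_table" not in spec:
        spec["probability_table"] = get_preset(cfg.preset)
    spec.setdefault("seed", cfg.seed)
    return generate_linked_datasets(SyntheticConfig(**spec))


def run_pipeline(cfg: RunConfig):
    """Execute every stage and return the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "perilink",
        "version": perilink.__version__,
        "seed": cfg.seed,
        "preset": cfg.preset,
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        # --- stage 1: obtain registers -----------------------------------
        truth = None
        if cfg.synthetic is not None:
            cohort, episodes, truth, genlog = _build_synthetic(cfg)
            write_records(cohort, out / "cohort.csv")
            write_records(episodes, out / "episodes.csv")
            truth.to_frame().to_csv(out / "truth.csv", index=False)
        else:
            cohort = read_records(cfg.inputs["cohort"], "cohort")
            episodes = read_records(cfg.inputs["episodes"], "episodes")
            if cfg.inputs.get("truth"):
                truth = TruthMap.from_frame(pd.read_csv(cfg.inputs["truth"]))
        record("registers", n_cohort=len(cohort), n_episodes=len(episodes),
               n_truth=len(truth) if truth is not None else None)

        # --- stage 2: candidate pairs + comparison vectors ----------------
        pt = get_preset(cfg.preset)
        fields = cfg.fields or [
            f for f in pt.fields if f in cohort.df.columns and f in episodes.df.columns
        ]
        if cfg.blocking_key:
            index = block_pairs(cohort, episodes, cfg.blocking_key, cfg.missing_policy)
        else:
            index = all_pairs(cohort, episodes)
        index.pairs.to_csv(out / "pairs.csv", index=False)
        cvs = compare_pairs(cohort, episodes, index, default_specs(fields))
        record("compare", n_pairs=len(index), total_possible=index.total_possible,
               blocking_key=cfg.blocking_key, fields=fields)

        # --- stage 3: scoring ---------------------------------------------
        scored: dict[str, pd.DataFrame] = {}
        for alg in cfg.algorithms:
            if alg == "fs":
                scored[alg] = fs_score_many(cvs, fs_weights(pt.subset(fields)))
            elif alg == "em":
                params = em_fit(cvs, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
                if params.converged:
                    scored[alg] = em_score_many(cvs, params)
                else:
                    logger.warning("EM did not converge (%s); no EM scores", params.message)
                    scored[alg] = pd.DataFrame(
                        columns=["cohort_id", "episode_id", "weight", "algorithm"]
                    )
                manifest["em"] = {
                    "converged": params.converged,
                    "iterations": params.iterations,
                    "p": None if pd.isna(params.p) else params.p,
                    "message": params.message,
                }
            elif alg == "epilink":
                scored[alg] = epilink_score_many(cvs, epilink_spec_from_table(pt.subset(fields)))
            scored[alg].to_csv(out / f"scores_{alg}.csv", index=False)
        record("score", **{alg: len(df) for alg, df in scored.items()})

        # --- stage 4: threshold tables ------------------------------------
        for alg, df in scored.items():
            tt = threshold_table(df, sorted(cfg.cutoffs.get(alg, [])), (len(cohort), len(episodes)))
            tt.to_csv(out / f"thresholds_{alg}.csv", index=False)
        record("thresholds", cutoffs=cfg.cutoffs)

        # --- stage 5: merge + clerical review -----------------------------
        runs = []
        linked_counts = {}
        for alg, df in scored.items():
            cut = cfg.review_cutoff.get(alg, 0.0)
            kept = df[df["weight"] > cut]
            linked_counts[alg] = len(kept)
            runs.append(kept)
        candidates = merge_candidates(runs)
        candidates.to_csv(out / "candidates.csv", index=False)

        review = None
        if cfg.review_mode != "none" and len(candidates):
            if cfg.review_mode == "oracle":
                if truth is None:
                    raise ValueError("oracle review requested but no truth map available")
                oracle = truth.oracle(complete=True)
            else:
                oracle = _interactive_oracle(candidates)
            review = clerical_review(candidates, oracle, max_rounds=cfg.review_max_rounds)
            pd.DataFrame(
                sorted(review.confirmed), columns=["cohort_id", "episode_id"]
            ).to_csv(out / "confirmed.csv", index=False)
        record(
            "review",
            n_candidates=len(candidates),
            linked_per_algorithm=linked_counts,
            n_confirmed=len(review.confirmed) if review else None,
            n_unresolved=len(review.unresolved) if review else None,
            rounds=review.rounds if review else None,
        )

        # --- stage 6: evaluation ------------------------------------------
        rows = []
        if review is not None and truth is not None:
            confirmed = review.confirmed
            for alg, df in scored.items():
                cut = cfg.review_cutoff.get(alg, 0.0)
                kept = df[df["weight"] > cut]
                linked = len(kept)
                kept_pairs = set(zip(kept["cohort_id"], kept["episode_id"]))
                tp = len(kept_pairs & confirmed)
                cells = error_cells(len(cohort), len(episodes), linked, tp, len(cohort))
                met = linkage_metrics(cells).rounded(3)
                rows.append(
                    {
                        "algorithm": alg,
                        "cutoff": cut,
                        "linked": linked,
                        "true_links": tp,
                        "sensitivity": met.sensitivity,
                        "ppv": met.ppv,
                        "specificity": met.specificity,
                        "npv": met.npv,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "evaluation.csv", index=False)
        record("evaluate", n_rows=len(rows))
    except Exception as exc:  # abort with the stage name in the manifest
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    return manifest


def _interactive_oracle(candidates: pd.DataFrame):
    """Terminal prompt loop; answers y/n/skip per displayed pair."""
    shown = candidates.set_index(["cohort_id", "episode_id"])

    def verdict(pair):
        row = shown.loc[pair]
        print(f"\ncandidate {pair[0]} ↔ {pair[1]}")
        print(row.to_string())
        while True:
            ans = input("match? [y/n/s(kip)] ").strip().lower()
            if ans in ("y", "yes"):
                return True
            if ans in ("n", "no"):
                return False
            if ans in ("s", "skip", ""):
                return None

    return verdict
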