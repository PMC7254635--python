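"""End-to-end orchestration: load/synthesise -> select k -> segment ->
classify -> profile, with a reproducible run manifest.

A single top-level seed is split deterministically per stage (synthesis,
k-selection subsets, k-means) via ``SeedSequence.spawn``, so partial
re-runs reproduce the corresponding stage exactly.  Segment ids in every
output use size ordering (segment 1 is the largest) for cross-run
comparability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, ID_COL, RunConfig, UTIL_COLS, read_cohort, write_cohort
from .profiling import profile_segments, run_test_battery
from .rules import characterisation, classify_segments
from .segmentation import (
    SegmentModel,
    fit_standardizer,
    kmeans_fit,
    relabel_by_size,
    select_k,
    stage_rng,
    transform,
)
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger("popsegment")


class PipelineError(Exception):
    pass


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    config: dict
    seed: int
    input_fingerprint: dict
    chosen_k: int
    k_selection: dict | None
    objective: float
    converged: bool
    outputs: list[str]
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _fingerprint(cohort: CohortTable) -> dict:
    cols = {}
    for col in (ID_COL,) + UTIL_COLS:
        data = cohort.df[col].astype(str).str.encode("utf-8").to_numpy()
        h = hashlib.sha256()
        for v in data:
            h.update(v)
        cols[col] = h.hexdigest()[:16]
    return {"n": cohort.n, "column_checksums": cols}


def run_pipeline(config: RunConfig, *,
                 input_path: str | Path | None = None,
                 generator: GeneratorConfig | None = None,
                 out_dir: str | Path = "popsegment_out",
                 k_override: int | None = None) -> RunManifest:
    """Execute the full analysis and write all artifacts plus a manifest.

    Exactly one of ``input_path`` (a cohort CSV) or ``generator`` (a
    synthetic-cohort configuration) must be given.  Unless ``k_override``
    is set, the cluster count comes from the subsampled selection
    procedure.  Any stage failure aborts with the stage name; partial
    outputs are removed.
    """
    if (input_path is None) == (generator is None):
        raise PipelineError("provide exactly one of input_path or generator")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "load"
        if generator is not None:
            logger.info("synthesising cohort: n=%d seed=%d", generator.n, generator.seed)
            cohort = generate_cohort(generator)
            path = out / "cohort.csv"
            write_cohort(cohort, path)
            written.append(path)
        else:
            logger.info("reading cohort from %s", input_path)
            cohort = read_cohort(input_path)

        trace_summary = None
        if k_override is not None:
            k = k_override
            logger.info("using k override: %d", k)
        else:
            stage = "select_k"
            logger.info("selecting k on %d subsets of %d (range %s)",
                        config.n_subsets, config.subset_size, config.k_range)
            trace = select_k(cohort, config)
            k = trace.chosen_k
            path = out / "kselection_trace.csv"
            trace.table.to_csv(path, index=False)
            written.append(path)
            trace_summary = {"chosen_k": k,
                             "suggestions": [s for s in trace.suggestions]}
            logger.info("consensus k = %d (suggestions %s)", k, trace.suggestions)

        stage = "kmeans"
        std = fit_standardizer(cohort)
        z = transform(std, cohort)
        model = kmeans_fit(
            z, k, rng=stage_rng(config.seed, stage=2),
            init=config.kmeans.init, restarts=config.kmeans.restarts,
            tol=config.kmeans.tol, max_iter=config.kmeans.max_iter)
        model = relabel_by_size(model)
        logger.info("k-means: objective=%.3f iterations=%d converged=%s",
                    model.objective, model.iterations, model.converged)

        assignments = pd.DataFrame({ID_COL: cohort.df[ID_COL],
                                    "segment": model.assignment})
        path = out / "assignments.csv"
        assignments.to_csv(path, index=False)
        written.append(path)

        cent = pd.DataFrame(model.centroids, columns=[f"z_{c}" for c in UTIL_COLS])
        raw = std.inverse_transform(model.centroids)
        for j, c in enumerate(UTIL_COLS):
            cent[c] = raw[:, j]
        cent.insert(0, "segment", np.arange(1, model.k + 1))
        path = out / "centroids.csv"
        cent.to_csv(path, index=False)
        written.append(path)

        stage = "profile"
        report = profile_segments(cohort, model.assignment)
        path = out / "profile.csv"
        report.table.to_csv(path, index_label="segment")
        written.append(path)

        stage = "classify"
        seg_means = report.segments[[f"{c}_mean" for c in UTIL_COLS]]
        seg_means.columns = list(UTIL_COLS)
        pop_means = report.table.loc["population",
                                     [f"{c}_mean" for c in UTIL_COLS]].to_numpy(float)
        labels = classify_segments(seg_means, pop_means, config)
        cls = pd.DataFrame([
            {"segment": lab.segment, "need": lab.need,
             "complexity": lab.complexity,
             "characterisation": characterisation(lab),
             "fired_criteria": json.dumps(lab.fired_criteria)}
            for lab in labels])
        path = out / "classification.csv"
        cls.to_csv(path, index=False)
        written.append(path)

        stage = "tests"
        battery = run_test_battery(cohort, model.assignment, alpha=config.alpha,
                                   welch=config.welch)
        for name, frame in (("tests_global.csv", battery.global_tests),
                            ("tests_pairwise.csv", battery.pairwise),
                            ("annotations.csv", battery.annotations)):
            path = out / name
            frame.to_csv(path, index=False)
            written.append(path)

        stage = "manifest"
        manifest = RunManifest(
            config=_config_dict(config),
            seed=config.seed,
            input_fingerprint=_fingerprint(cohort),
            chosen_k=k,
            k_selection=trace_summary,
            objective=model.objective,
            converged=model.converged,
            outputs=[p.name for p in written],
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )
        (out / "manifest.json").write_text(manifest.to_json())
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["k_range"] = list(d["k_range"])
    return d


def fit_segments(cohort: CohortTable, k: int, config: RunConfig) -> SegmentModel:
    """Standardise, fit k-means at k, and renumber segments by size."""
    std = fit_standardizer(cohort)
    model = kmeans_fit(
        transform(std, cohort), k, rng=stage_rng(config.seed, stage=2),
        init=config.kmeans.init, restarts=config.kmeans.restarts,
        tol=config.kmeans.tol, max_iter=config.kmeans.max_iter)
    return relabel_by_size(model)


__all__ = ["RunManifest", "run_pipeline", "fit_segments", "PipelineError"]
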