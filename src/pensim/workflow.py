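"""Top-level staged workflow: bundle -> baseline -> ensemble -> analyses.

``run_all`` executes every stage of the pipeline against a run
configuration, writing CSV outputs plus a manifest (seed, config hash,
package version). Stages whose outputs already exist under a matching
manifest are skipped, so deleting one output regenerates only that stage
and the run is idempotent for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__, analysis, engine, indicators
from .config import PARAMETER_NAMES, RunConfig, save_config
from .synthetic import SynthConfig, generate_bundle, read_bundle, write_bundle

__all__ = ["run_all"]


def _config_hash(config: RunConfig) -> str:
    import io
    buf = io.StringIO()
    import yaml
    from .config import _to_plain
    yaml.safe_dump(_to_plain(config), buf, sort_keys=True)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


def run_all(config: RunConfig, n_influence_paths: int | None = None,
            log=print) -> dict:
    """Execute synth, baseline, simulate, sensitivity, influence, and
    backtrack stages; returns the in-memory results keyed by stage."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle_dir = Path(config.bundle_dir)
    manifest_path = out_dir / "manifest.json"
    cfg_hash = _config_hash(config)
    manifest = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    if manifest.get("config_hash") != cfg_hash:
        manifest = {"config_hash": cfg_hash, "seed": config.seed,
                    "version": __version__, "stages": {}}

    def done(stage, files):
        fresh = all((out_dir / f).exists() for f in files)
        return fresh and stage in manifest["stages"]

    def mark(stage, files):
        manifest["stages"][stage] = files
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    results = {}

    # --- synth -------------------------------------------------------------
    if not (bundle_dir / "initial_conditions.csv").exists():
        log(f"[synth] generating pseudo-yearbook bundle in {bundle_dir}")
        write_bundle(generate_bundle(SynthConfig(seed=config.seed)),
                     bundle_dir)
    bundle = read_bundle(bundle_dir)
    results["bundle"] = bundle

    fitted = engine.fit_from_bundle(bundle, config.policy,
                                    config.randomization)
    results["fitted"] = fitted

    # --- baseline ----------------------------------------------------------
    files = ["baseline_indicators.csv", "baseline_aging.csv"]
    if not done("baseline", files):
        log("[baseline] fixed-parameter scenario")
        base = engine.run_fixed_scenario(fitted, config.policy)
        base["table"].to_csv(out_dir / files[0], index=False)
        from .population import aging_indicators
        aging_indicators(base["demography"].ledgers).to_csv(
            out_dir / files[1], index=False)
        mark("baseline", files)
        results["baseline"] = base

    # --- simulate ----------------------------------------------------------
    files = ["ensemble_summary.csv", "final_balances.csv"]
    if not done("simulate", files):
        log(f"[simulate] Monte Carlo, {config.n_paths} paths")
        result = engine.run_monte_carlo(fitted, config.policy,
                                        n_paths=config.n_paths,
                                        seed=config.seed, progress=True)
        result.summary().to_csv(out_dir / files[0], index=False)
        pd.DataFrame({"path": range(result.n_paths),
                      "final_balance": result.final_balance}).to_csv(
            out_dir / files[1], index=False)
        mark("simulate", files)
        results["simulation"] = result

    # --- sensitivity -------------------------------------------------------
    files = ["sensitivity.csv"]
    if not done("sensitivity", files):
        log("[sensitivity] tau scan over the nine parameters")
        frames = []
        for name in PARAMETER_NAMES:
            scan = analysis.elasticity_scan(fitted, config.policy, name)
            frame = scan.to_frame()
            frame["direction"] = scan.direction
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(out_dir / files[0],
                                                    index=False)
        mark("sensitivity", files)

    # --- influence ---------------------------------------------------------
    files = ["influence.csv"]
    if not done("influence", files):
        n_inf = n_influence_paths or max(200, config.n_paths // 10)
        log(f"[influence] index A per parameter, {n_inf} paths each")
        ranking = analysis.influence_ranking(fitted, config.policy,
                                             n_paths=n_inf,
                                             seed=config.seed)
        ranking.to_csv(out_dir / files[0], index=False)
        mark("influence", files)

    # --- backtrack ---------------------------------------------------------
    files = ["backtrack.csv"]
    if not done("backtrack", files):
        log("[backtrack] decile feature search")
        result = results.get("simulation")
        if result is None:
            result = engine.run_monte_carlo(fitted, config.policy,
                                            n_paths=config.n_paths,
                                            seed=config.seed)
        report = analysis.backtrack(result)
        report.to_frame().to_csv(out_dir / files[0], index=False)
        mark("backtrack", files)

    save_config(config, out_dir / "run_config.yaml")
    return results
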