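"""End-to-end orchestration: encode -> discover -> weight -> select -> evaluate.

A run is described by a single YAML/dict config and is a pure function of
(config, seed): every stochastic stage draws from a generator spawned off
the run seed, every intermediate artifact is persisted under a
config-hash-named directory, and re-running the same config reproduces all
numeric outputs byte for byte.

Stage order (mirroring the classification workflow):

1. corpus        — load hairpin files, or generate a synthetic corpus
2. encode        — ss-strings for every record
3. split         — per-class train/test partition
4. discover      — per-class maximal-motif catalogs over the full class sets
5. merge         — deduplicated joint catalog
6. weight        — linear-SVM normal-based weights on the training matrix
7. select        — incremental top-N accuracy curve, best model
8. evaluate      — held-out metrics and ROC/AUC
9. stats         — optional RSS / family / position analyses
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ssio
from .classify import (
    build_feature_matrix,
    compute_feature_weights,
    evaluate,
    incremental_selection,
    rank_motifs,
    roc_auc,
    train_svm,
)
from .discovery import MotifCatalog, SSMotif, discover_motifs, merge_catalogs
from .hairpins import Hairpin, filter_redundant, is_single_loop, split_train_test
from .stats import family_similarity_test, normalized_positions, rss_pvalues
from .synth import GeneratorConfig, SynthCorpus, make_corpus, write_corpus

__all__ = ["RunConfig", "run_pipeline"]

_DEFAULTS = {
    "seed": None,
    "out_root": "runs",
    "input": None,  # {"vienna": ..., "labels": ..., "annotations": ...}
    "synth": None,  # GeneratorConfig fields
    "filter": {"single_loop": True, "identity": None},
    "discovery": {"L": 4, "W": 12, "K": None, "K_fraction": 0.75, "max_len": None, "metric": "char"},
    "split": {"train_fraction": 484 / 608},
    "classifier": {
        "kernel": "linear",
        "C": 1.0,
        "gamma": None,
        "step": 100,
        "feature_mode": "count",
        "rank_mode": "abs",
    },
    "stats": {"rss_reps": 0, "family_reps": 0, "position_motifs": []},
}


def _merge(defaults: dict, user: dict) -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict) and isinstance(user.get(k), dict):
            out[k] = {**v, **user[k]}
        elif k in user:
            out[k] = user[k]
        else:
            out[k] = v
    for k in user:
        if k not in defaults:
            raise ValueError(f"unknown config key {k!r}")
    return out


class RunConfig:
    """Validated run configuration (see module docstring for the stage map)."""

    def __init__(self, data: dict):
        self.data = _merge(_DEFAULTS, data)
        if self.data["seed"] is None:
            raise ValueError("config must set a seed (every stochastic stage draws from it)")
        if (self.data["input"] is None) == (self.data["synth"] is None):
            raise ValueError("config must set exactly one of 'input' or 'synth'")
        if self.data["input"] is not None:
            for key, path in self.data["input"].items():
                if path is not None and not Path(path).exists():
                    raise ValueError(f"input file for {key!r} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _load_corpus(config: RunConfig, rng: np.random.Generator) -> tuple[list[Hairpin], dict]:
    if config["synth"] is not None:
        synth_fields = dict(config["synth"])
        synth_fields.setdefault("seed", int(rng.integers(2**31)))
        for key in ("length_range", "stem_range", "loop_range", "family_blocks"):
            if key in synth_fields and isinstance(synth_fields[key], list):
                synth_fields[key] = tuple(synth_fields[key])
        for key in ("positive_motifs", "negative_motifs"):
            if synth_fields.get(key) is not None:
                synth_fields[key] = tuple(synth_fields[key])
        corpus = make_corpus(GeneratorConfig(**synth_fields))
        return corpus.all_hairpins, corpus.manifest
    paths = config["input"]
    hairpins = ssio.load_hairpins(
        vienna=paths.get("vienna"),
        fasta=paths.get("fasta"),
        structures=paths.get("structures"),
        labels=paths.get("labels"),
        annotations=paths.get("annotations"),
    )
    return hairpins, {}


def run_pipeline(config: RunConfig | dict) -> Path:
    """Execute all enabled stages; returns the run directory."""
    if isinstance(config, dict):
        config = RunConfig(config)
    run_dir = Path(config["out_root"]) / f"run_{config.hash}"
    run_dir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(int(config["seed"]))
    stage_rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("corpus", "split", "stats"), seed_seq.spawn(3)
        )
    }
    log: dict = {
        "config": config.data,
        "config_hash": config.hash,
        "stages": [],
        "versions": _versions(),
    }
    current_stage = "corpus"

    def done(name, **info):
        log["stages"].append({"stage": name, "status": "ok", **info})

    try:
        # 1-2. corpus + encode ------------------------------------------------
        hairpins, manifest = _load_corpus(config, stage_rngs["corpus"])
        if config["filter"]["single_loop"]:
            hairpins = [hp for hp in hairpins if is_single_loop(hp.structure)]
        if config["filter"]["identity"] is not None:
            hairpins = filter_redundant(hairpins, config["filter"]["identity"])
        positives = [hp for hp in hairpins if hp.label == "positive"]
        negatives = [hp for hp in hairpins if hp.label == "negative"]
        if not positives or not negatives:
            raise ValueError("corpus must contain both positive and negative hairpins")
        if manifest:
            write_corpus(
                SynthCorpus(positives=positives, negatives=negatives, manifest=manifest),
                run_dir / "corpus",
            )
        ss_map = {hp.id: hp.encode() for hp in hairpins}
        with open(run_dir / "ss_strings.tsv", "w") as fh:
            for hp in hairpins:
                fh.write(f"{hp.id}\t{ss_map[hp.id].text}\n")
        done("corpus", n_positive=len(positives), n_negative=len(negatives))

        # 3. split ------------------------------------------------------------
        current_stage = "split"
        n_train = int(round(config["split"]["train_fraction"] * min(len(positives), len(negatives))))
        train, test = split_train_test(positives, negatives, n_train, stage_rngs["split"])
        done("split", n_train_per_class=n_train)

        # 4-5. discover + merge ----------------------------------------------
        current_stage = "discover"
        disc = config["discovery"]
        catalogs = {}
        for label, group in (("positive", positives), ("negative", negatives)):
            K = disc["K"] if disc["K"] is not None else int(round(disc["K_fraction"] * len(group)))
            catalogs[label] = discover_motifs(
                [ss_map[hp.id] for hp in group],
                L=disc["L"],
                W=disc["W"],
                K=K,
                max_len=disc["max_len"],
                metric=disc["metric"],
                origin=label,
            )
            catalogs[label].to_tsv(run_dir / f"catalog_{label}.tsv")
        merged = merge_catalogs(catalogs["positive"], catalogs["negative"])
        merged.to_tsv(run_dir / "catalog_merged.tsv")
        done(
            "discover",
            n_positive_motifs=len(catalogs["positive"]),
            n_negative_motifs=len(catalogs["negative"]),
            n_merged=len(merged),
        )

        # 6. weight + rank ----------------------------------------------------
        current_stage = "weight"
        clf = config["classifier"]
        fm_train = build_feature_matrix(
            merged, [(hp, ss_map[hp.id]) for hp in train], mode=clf["feature_mode"]
        )
        y_train = [hp.label for hp in train]
        linear_model = train_svm(
            fm_train, y_train, kernel="linear", C=clf["C"], feature_mode=clf["feature_mode"]
        )
        weights = compute_feature_weights(linear_model)
        ranked, order = rank_motifs(merged, weights, mode=clf["rank_mode"])
        ranked.to_tsv(run_dir / "ranked_catalog.tsv")
        done("weight", n_features=len(merged))

        # 7. select -----------------------------------------------------------
        current_stage = "select"
        fm_test = build_feature_matrix(
            merged, [(hp, ss_map[hp.id]) for hp in test], mode=clf["feature_mode"]
        )
        y_test = [hp.label for hp in test]
        selection = incremental_selection(
            ranked,
            fm_train.X[:, order],
            y_train,
            fm_test.X[:, order],
            y_test,
            step=clf["step"],
            kernel=clf["kernel"],
            C=clf["C"],
            gamma=clf["gamma"],
            feature_mode=clf["feature_mode"],
        )
        selection.curve.to_csv(run_dir / "accuracy_curve.tsv", sep="\t", index=False)
        selection.best_model.save(run_dir / "best_model.json")
        done("select", best_n=selection.best_n)

        # 8. evaluate ---------------------------------------------------------
        current_stage = "evaluate"
        n_best = selection.best_n
        scores = selection.best_model.decision_function(fm_test.X[:, order][:, :n_best])
        preds = np.where(scores > 0, 1, -1)
        report = evaluate(preds, y_test)
        roc_points, auc = roc_auc(scores, y_test)
        report.roc_points, report.auc = roc_points, auc
        pd.DataFrame([report.as_dict()]).to_csv(run_dir / "metrics.tsv", sep="\t", index=False)
        pd.DataFrame(roc_points, columns=["fpr", "tpr"]).to_csv(
            run_dir / "roc.tsv", sep="\t", index=False
        )
        (run_dir / "metrics.txt").write_text(report.pretty() + "\n")
        done("evaluate", best_n=n_best, acc=report.acc, sp=report.sp, se=report.se, auc=auc)

        # 9. stats ------------------------------------------------------------
        current_stage = "stats"
        stats_cfg = config["stats"]
        stats_rng = stage_rngs["stats"]
        if stats_cfg["rss_reps"]:
            pos_motifs = [r.motif for r in merged if r.origin in ("positive", "both")]
            pos_ss = [ss_map[hp.id] for hp in positives]
            rss = rss_pvalues(pos_motifs, pos_ss, n_reps=stats_cfg["rss_reps"], seed=stats_rng)
            rss.to_dataframe().to_csv(run_dir / "stats_rss.tsv", sep="\t", index=False)
        if stats_cfg["family_reps"] and manifest.get("families"):
            all_pos_ss = [ss_map[hp.id] for hp in positives]
            rows = []
            for fam_id, members in manifest["families"].items():
                fam_ss = [ss_map[m] for m in members if m in ss_map]
                res = family_similarity_test(
                    fam_ss, all_pos_ss, merged, n_reps=stats_cfg["family_reps"], seed=stats_rng
                )
                rows.append(
                    {
                        "family": fam_id,
                        "size": len(fam_ss),
                        "common_motifs": res.observed_common,
                        "p_value": res.p_value,
                    }
                )
            pd.DataFrame(rows).to_csv(run_dir / "stats_family.tsv", sep="\t", index=False)
        for i, motif_text in enumerate(stats_cfg["position_motifs"]):
            profile = normalized_positions(SSMotif.from_text(motif_text), positives)
            profile.to_dataframe().to_csv(
                run_dir / f"positions_{i}.tsv", sep="\t", index=False
            )
        done("stats")
    except Exception as exc:
        log["stages"].append({"stage": current_stage, "status": "failed", "error": str(exc)})
        with open(run_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    with open(run_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return run_dir


def _versions() -> dict:
    import sklearn

    from . import __version__

    return {
        "ssmotif": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
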