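"""End-to-end orchestration: simulate (or ingest) -> preprocess ->
featurize -> classify -> infer, reproducible from one master seed.

The master seed fans out to per-stage seeds through a stable derivation,
so a saved RunConfig re-run reproduces every output. Results embed the
config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import _derive_seed
from .edfio import read_edf, write_edf
from .features import (FeatureTable, FeatureVector, WelchParams, assemble_table,
                       session_features)
from .inference import (RandomizationResult, TransferResult, cross_lag_transfer,
                        randomization_test, subgroup_test)
from .preprocess import PreprocessParams, preprocess_block
from .simulate import (LAGS, CohortConfig, Recording,
                       draw_subject_offsets, generate_block, session_blocks)


@dataclass
class RunConfig:
    """Everything one study run needs; serializable to YAML/JSON."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    edf_manifest: str | None = None      # ingest real EDFs instead of simulating
    run_preprocessing: bool = True
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    welch: WelchParams = field(default_factory=WelchParams)
    contrasts: tuple = (("pre", "post1h"), ("pre", "post24h"))
    n_seeds: int = 100
    n_trials: int = 64
    k: int = 5
    strategy: str = "tpe"
    shuffle_mode: str = "uniform"
    run_subgroups: bool = True
    run_transfer: bool = True
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "welch" in d and isinstance(d["welch"], dict):
            d["welch"] = WelchParams(**d["welch"])
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _iter_sessions(config: RunConfig):
    """Yield (subject_id, lag, [blocks]) one session at a time (bounded
    memory even for full-size cohorts)."""
    cohort = config.cohort
    if config.edf_manifest is not None:
        yield from _iter_edf_sessions(config)
        return
    offsets = {sid: draw_subject_offsets(cohort, i)
               for i, sid in enumerate(cohort.subject_ids())}
    for sid in cohort.subject_ids():
        for lag in LAGS:
            blocks = [generate_block(cohort, sid, sess, offsets[sid])[0]
                      for sess in session_blocks(lag)]
            yield sid, lag, blocks


def _iter_edf_sessions(config: RunConfig):
    """Sessions from a JSON manifest of EDF files: entries with path,
    subject_id, group, lag, block_index."""
    manifest = json.loads(Path(config.edf_manifest).read_text())
    by_session: dict[tuple[str, str], list[dict]] = {}
    for entry in manifest["blocks"]:
        by_session.setdefault((entry["subject_id"], entry["lag"]), []).append(entry)
    root = Path(config.edf_manifest).parent
    for (sid, lag), entries in sorted(by_session.items()):
        blocks = []
        for e in sorted(entries, key=lambda e: e["block_index"]):
            edf = read_edf(root / e["path"])
            sess = [s for s in session_blocks(lag)
                    if s.block_index == e["block_index"]][0]
            blocks.append(Recording(
                subject_id=sid, group=e["group"], session=sess, fs=edf.fs,
                data=edf.data, channel_names=edf.channel_names))
        yield sid, lag, blocks


def compute_features(config: RunConfig, log=None) -> list[FeatureVector]:
    """Stages 1-3: simulate/ingest, preprocess, featurize every session."""
    vectors = []
    for sid, lag, blocks in _iter_sessions(config):
        if config.run_preprocessing:
            blocks = [preprocess_block(b, config.cohort.montage,
                                       config.preprocess) for b in blocks]
        vectors.append(session_features(blocks, config.welch,
                                        config.cohort.bands))
        if log:
            log(f"featurized {sid} {lag}")
    return vectors


@dataclass
class ResultBundle:
    config: RunConfig
    tables: dict                      # contrast name -> FeatureTable
    randomization: dict               # contrast name -> RandomizationResult
    subgroups: dict                   # (contrast, group) -> RandomizationResult
    transfer: tuple | None            # (TransferResult, TransferResult)

    def summary(self) -> dict:
        def _rr(r: RandomizationResult) -> dict:
            return {"mean_true": float(np.mean(r.true_scores)),
                    "mean_shuffled": float(np.mean(r.shuffled_scores)),
                    "effect": r.effect, "t": r.comparison.t,
                    "df": r.comparison.df, "p": r.comparison.p}

        out = {"version": __version__, "config_hash": self.config.digest(),
               "randomization": {c: _rr(r) for c, r in self.randomization.items()},
               "subgroups": {f"{c}:{g}": _rr(r)
                             for (c, g), r in self.subgroups.items()}}
        if self.transfer:
            out["transfer"] = {
                t.train_lag: {
                    "same_lag_sensitivity": float(np.mean(t.same_lag)),
                    "cross_lag_sensitivity": float(np.mean(t.cross_lag)),
                    **{name: {"t": w.t, "df": w.df, "p": w.p}
                       for name, w in t.comparisons.items()}}
                for t in self.transfer}
        return out


def run_pipeline(config: RunConfig, out_dir=None, verbose: bool = False
                 ) -> ResultBundle:
    """Execute the full study analysis described by ``config``.

    Writes, when ``out_dir`` is given: the resolved config, per-contrast
    feature tables (CSV), score distributions (CSV) and a results JSON
    carrying the config hash and package version.
    """
    log = print if verbose else None
    try:
        vectors = compute_features(config, log=log)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'featurize' failed: {e}") from e

    tables: dict[str, FeatureTable] = {}
    for lags in config.contrasts:
        name = f"{lags[0]}_vs_{lags[1]}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables[name] = assemble_table(vectors, lags=tuple(lags))

    seed = config.master_seed
    randomization, subgroups = {}, {}
    for name, table in tables.items():
        randomization[name] = randomization_test(
            table, n_seeds=config.n_seeds, n_trials=config.n_trials,
            base_seed=_derive_seed(seed, "rand", name),
            strategy=config.strategy, k=config.k,
            shuffle_mode=config.shuffle_mode)
        if log:
            log(f"{name}: {randomization[name].comparison}")
        if config.run_subgroups:
            for group in ("kicking", "non_kicking"):
                subgroups[(name, group)] = subgroup_test(
                    table, group, n_seeds=config.n_seeds,
                    n_trials=config.n_trials,
                    base_seed=_derive_seed(seed, "sub", name, group),
                    strategy=config.strategy, k=config.k,
                    shuffle_mode=config.shuffle_mode)

    transfer = None
    if config.run_transfer and len(tables) >= 2:
        a, b = list(tables.values())[:2]
        transfer = cross_lag_transfer(
            a, b, n_seeds=config.n_seeds, n_trials=config.n_trials,
            base_seed=_derive_seed(seed, "transfer"), strategy=config.strategy,
            k=config.k, shuffle_mode=config.shuffle_mode)

    bundle = ResultBundle(config=config, tables=tables,
                          randomization=randomization, subgroups=subgroups,
                          transfer=transfer)
    if out_dir is not None:
        _write_outputs(bundle, Path(out_dir))
    return bundle


def _write_outputs(bundle: ResultBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.config.save(out_dir / "config.yaml")
    for name, table in bundle.tables.items():
        table.to_csv(out_dir / f"features_{name}.csv")
    for name, r in bundle.randomization.items():
        np.savetxt(out_dir / f"scores_{name}.csv",
                   np.column_stack([r.true_scores, r.shuffled_scores]),
                   delimiter=",", header="true,shuffled", comments="")
    (out_dir / "results.json").write_text(
        json.dumps(bundle.summary(), indent=2, default=float))


def export_cohort_edf(config: CohortConfig, out_dir, *,
                      session_per_file: bool = True) -> Path:
    """Write a synthetic cohort as EDF files plus a JSON manifest that
    :class:`RunConfig` (edf_manifest) can ingest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    offsets = {sid: draw_subject_offsets(config, i)
               for i, sid in enumerate(config.subject_ids())}
    entries = []
    for sid in config.subject_ids():
        for lag in LAGS:
            for sess in session_blocks(lag):
                rec, _ = generate_block(config, sid, sess, offsets[sid])
                name = f"{sid}_{lag}_b{sess.block_index}.edf"
                write_edf(out / name, rec.data, rec.fs, rec.channel_names,
                          patient_id=sid, recording_id=f"{lag} {sess.condition}")
                entries.append({"path": name, "subject_id": sid,
                                "group": rec.group, "lag": lag,
                                "block_index": sess.block_index})
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"blocks": entries}, indent=2))
    return manifest
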