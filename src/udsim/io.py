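"""Scenario files, trajectory CSV serialisation and report writing.

Scenario files are YAML or JSON mappings of :class:`~udsim.simulate.ScenarioConfig`
fields; unknown keys are rejected so typos cannot silently fall back to
defaults.  Trajectory CSVs carry a commented provenance header (schema version,
package version, the fully resolved configuration and the termination reason)
so any output file can be regenerated from its own header, followed by one row
per recorded generation: the generation number, the 18 allele-frequency columns
labelled with the standard allele names, and optionally the 2025 genotype
columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alleles import Locus, N_ALLELES, enumerate_alleles, genotype_from_label
from .mutation import MutationModel
from .simulate import ReleaseEvent, ScenarioConfig, Trajectory, allele_labels

__all__ = [
    "SCHEMA_VERSION",
    "ScenarioError",
    "load_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "write_trajectory",
    "read_trajectory",
    "write_mutation_matrix",
]

SCHEMA_VERSION = 1

try:
    _VERSION = version("udsim")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _VERSION = "unknown"


class ScenarioError(ValueError):
    """Scenario-file validation failure, with field-level messages."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


_SCALAR_KEYS = {
    "eps_A": float,
    "eps_B": float,
    "eps_AM": float,
    "eps_BM": float,
    "m": float,
    "generations": int,
    "record_genotypes": bool,
    "record_mean_fitness": bool,
    "thin": int,
    "wild_threshold": float,
    "cargo_threshold": float,
}
_OPTIONAL_KEYS = {"stop_at_wild_freq": float, "convergence_tol": float}
_RELEASE_KEYS = {"generation", "genotype", "alpha"}


def scenario_from_dict(data: dict) -> ScenarioConfig:
    """Build and validate a :class:`ScenarioConfig` from a plain mapping."""
    if not isinstance(data, dict):
        raise ScenarioError(["scenario file must contain a mapping"])
    data = dict(data)
    errors: list[str] = []
    sv = data.pop("schema_version", SCHEMA_VERSION)
    if sv != SCHEMA_VERSION:
        errors.append(f"schema_version: expected {SCHEMA_VERSION}, got {sv}")

    kwargs: dict = {}
    for key, typ in {**_SCALAR_KEYS, **_OPTIONAL_KEYS}.items():
        if key in data:
            raw = data.pop(key)
            if raw is None and key in _OPTIONAL_KEYS:
                continue
            try:
                kwargs[key] = typ(raw)
            except (TypeError, ValueError):
                errors.append(f"{key}: cannot interpret {raw!r} as {typ.__name__}")

    if "releases" in data:
        releases = []
        raw_releases = data.pop("releases")
        if not isinstance(raw_releases, list):
            errors.append("releases: must be a list of mappings")
            raw_releases = []
        for k, entry in enumerate(raw_releases):
            if not isinstance(entry, dict) or set(entry) != _RELEASE_KEYS:
                errors.append(
                    f"releases[{k}]: must be a mapping with keys {sorted(_RELEASE_KEYS)}"
                )
                continue
            try:
                releases.append(
                    ReleaseEvent(
                        int(entry["generation"]),
                        genotype_from_label(str(entry["genotype"])),
                        float(entry["alpha"]),
                    )
                )
            except ValueError as exc:
                errors.append(f"releases[{k}]: {exc}")
        kwargs["releases"] = releases

    if data:
        errors.append(f"unknown keys: {sorted(data)}")
    if errors:
        raise ScenarioError(errors)

    cfg = ScenarioConfig(**kwargs)
    try:
        cfg.validate()
    except ValueError as exc:
        raise ScenarioError(str(exc).split("; ")) from exc
    return cfg


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    """Fully resolved, JSON-serialisable form of a configuration."""
    d = asdict(cfg)
    d["releases"] = [
        {"generation": r.generation, "genotype": r.genotype.label, "alpha": r.alpha}
        for r in cfg.releases
    ]
    d["schema_version"] = SCHEMA_VERSION
    return d


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ScenarioError([f"cannot read scenario file {path}: {exc}"]) from exc
    try:
        data = yaml.safe_load(text)  # JSON is a YAML subset
    except yaml.YAMLError as exc:
        raise ScenarioError([f"cannot parse scenario file {path}: {exc}"]) from exc
    return scenario_from_dict(data)


def write_trajectory(tr: Trajectory, path: str | Path, include_genotypes: bool = False) -> None:
    """Write a trajectory CSV with a commented provenance header."""
    path = Path(path)
    header_meta = {
        "schema_version": SCHEMA_VERSION,
        "package_version": _VERSION,
        "termination": tr.termination,
        "config": scenario_to_dict(tr.config) if tr.config is not None else None,
    }
    df = tr.to_dataframe(include_genotypes=include_genotypes)
    try:
        with path.open("w") as fh:
            fh.write(f"# udsim-trajectory {json.dumps(header_meta)}\n")
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory` (bit-exact)."""
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# udsim-trajectory "):
            meta = json.loads(first[len("# udsim-trajectory "):])
        df = pd.read_csv(fh, comment="#", float_precision="round_trip")
    labels = allele_labels()
    cfg = None
    if meta.get("config") is not None:
        cfg = scenario_from_dict(meta["config"])
    geno_cols = [c for c in df.columns if "|" in c]
    return Trajectory(
        generations=df["generation"].to_numpy(dtype=np.int64),
        allele_freq_A=df[list(labels[:N_ALLELES])].to_numpy(dtype=float),
        allele_freq_B=df[list(labels[N_ALLELES:])].to_numpy(dtype=float),
        genotype_freqs=df[geno_cols].to_numpy(dtype=float) if geno_cols else None,
        mean_fitness=df["mean_fitness"].to_numpy() if "mean_fitness" in df else None,
        releases=list((cfg.releases if cfg else [])),
        config=cfg,
        termination=meta.get("termination", "unknown"),
    )


def write_mutation_matrix(mm: MutationModel, path: str | Path, locus: Locus | str = Locus.A) -> None:
    """Export the labelled 9 x 9 per-locus mutation matrix as CSV."""
    labels = [a.label for a in enumerate_alleles(Locus(locus))]
    pd.DataFrame(mm.matrix, index=labels, columns=labels).to_csv(Path(path))
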