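"""Plain-text (YAML) configuration parsing for simulations and experiments."""

from __future__ import annotations

import os

import numpy as np
import yaml

from .simulate import (
    CovarianceSpec,
    ErrorFamily,
    MeanProfileSet,
    SimulationConfig,
    synthetic_signal,
)


def _means_from_dict(spec: dict) -> tuple[MeanProfileSet, CovarianceSpec | None]:
    kind = spec.get("kind", "explicit")
    if kind == "synthetic_signal":
        return synthetic_signal(
            d=int(spec.get("d", 6)),
            strength=float(spec.get("strength", 1.0)),
            seed=spec.get("seed"),
        )
    if kind == "explicit":
        means = MeanProfileSet(
            doses=np.asarray(spec["doses"], float),
            mu0=np.asarray(spec["mu0"], float),
            mu1=np.asarray(spec["mu1"], float),
            mu2=np.asarray(spec["mu2"], float),
        )
        return means, None
    raise ValueError(f"unknown means kind {kind!r}")


def _covariance_from_dict(spec: dict) -> CovarianceSpec:
    return CovarianceSpec(
        family=spec.get("family", "independent"),
        rho=float(spec.get("rho", 0.0)),
        scale=np.asarray(spec["scale"], float) if "scale" in spec else 1.0,
        matrix=np.asarray(spec["matrix"], float) if spec.get("matrix") is not None else None,
    )


def _errors_from_dict(spec: dict) -> ErrorFamily:
    return ErrorFamily(
        kind=spec.get("kind", "gaussian"),
        gamma_shape=float(spec.get("gamma_shape", 8.0)),
        gamma_scale=float(spec.get("gamma_scale", 0.125)),
        laplace_scale=float(spec.get("laplace_scale", 0.25)),
    )


def simulation_config_from_dict(doc: dict) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML mapping."""
    means, signal_cov = _means_from_dict(doc.get("means", {"kind": "synthetic_signal"}))
    if "covariance" in doc:
        cov = _covariance_from_dict(doc["covariance"])
    elif signal_cov is not None:
        cov = signal_cov
    else:
        cov = CovarianceSpec()
    return SimulationConfig(
        means=means,
        covariance=cov,
        errors=_errors_from_dict(doc.get("errors", {})),
        effect_size=float(doc.get("effect_size", 1.0)),
        n=int(doc.get("n", 500)),
        maf=float(doc.get("maf", 0.5)),
        replicates_per_individual=int(doc.get("replicates_per_individual", 1)),
        seed=int(doc.get("seed", 0)),
        n_snps=int(doc.get("n_snps", 1)),
    )


def load_simulation_config(path: str | os.PathLike) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return simulation_config_from_dict(doc)
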