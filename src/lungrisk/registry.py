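"""Model registry: versioned coefficient payloads loaded from config files.

Each risk calculator is described by a YAML payload (one file per model)
holding its linear-predictor coefficients, centering constants, category
weights, baseline-risk tables or TSCE rate parameters. Code carries model
structure only; the numbers live in the configs, with provenance noted in
each file, and every loaded payload is checksummed so reports can cite the
exact coefficient version they used.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

__all__ = ["ModelSpec", "RegistryError", "MODEL_IDS", "load_payload", "get_model",
           "build_model", "payload_checksums"]

MODEL_IDS = (
    "bach",
    "llp",
    "llp_simplified",
    "plcom2012",
    "plcom2012_simplified",
    "tsce_incidence",
    "knoke",
    "tsce_cps_death",
    "tsce_nhs_hpfs_death",
)

_CONFIG_FILES = {
    "plcom2012": "plcom2012.yaml",
    "plcom2012_simplified": "plcom2012_simplified.synthetic.yaml",
    "llp": "llp.synthetic.yaml",
    "llp_simplified": "llp_simplified.synthetic.yaml",
    "bach": "bach.synthetic.yaml",
    "knoke": "knoke.synthetic.yaml",
    "tsce_incidence": "tsce_incidence.synthetic.yaml",
    "tsce_cps_death": "tsce_cps_death.synthetic.yaml",
    "tsce_nhs_hpfs_death": "tsce_nhs_hpfs_death.synthetic.yaml",
}


class RegistryError(KeyError):
    """Unknown model id or malformed payload."""


@dataclass(frozen=True)
class ModelSpec:
    """Identity card of one registered model."""

    model_id: str
    outcome: str  # "incidence" or "death"
    horizon: float  # native prediction time frame (years)
    covariates: tuple[str, ...]
    checksum: str  # sha256 of the payload file


def _read_config_text(model_id: str) -> str:
    try:
        fname = _CONFIG_FILES[model_id]
    except KeyError:
        raise RegistryError(f"unknown model id {model_id!r}; known: {MODEL_IDS}") from None
    return resources.files("lungrisk.config").joinpath(fname).read_text(encoding="utf-8")


def load_payload(model_id: str) -> tuple[dict, str]:
    """Load a model's coefficient payload and its sha256 checksum."""
    text = _read_config_text(model_id)
    checksum = hashlib.sha256(text.encode("utf-8")).hexdigest()
    payload = yaml.safe_load(text)
    if payload.get("model_id") != model_id:
        raise RegistryError(f"payload file for {model_id!r} declares {payload.get('model_id')!r}")
    return payload, checksum


def payload_checksums() -> dict[str, str]:
    """sha256 checksum of every registered coefficient file (provenance)."""
    return {mid: load_payload(mid)[1] for mid in MODEL_IDS}


_cache: dict[str, object] = {}


def get_model(model_id: str):
    """Return the (cached) risk model registered under ``model_id``."""
    if model_id not in _cache:
        payload, checksum = load_payload(model_id)
        _cache[model_id] = build_model(payload, checksum)
    return _cache[model_id]


def build_model(payload: dict, checksum: Optional[str] = None):
    """Construct a risk model from an in-memory payload (used by the
    registry and by tests that inject toy payloads)."""
    from . import models as _models

    if checksum is None:
        checksum = hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode("utf-8")
        ).hexdigest()
    form = payload.get("form")
    builders = {
        "logistic": _models.LogisticRiskModel,
        "llp_odds": _models.LLPModel,
        "annual_cycle": _models.AnnualCycleModel,
        "tsce": _models.TSCEModel,
    }
    try:
        cls = builders[form]
    except KeyError:
        raise RegistryError(f"unknown model form {form!r}") from None
    return cls(payload, checksum)
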