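"""Synthetic respondent populations for the two-factor severity scale.

The generator draws latent severities from a zero-mean bivariate normal
with unit variances and a configurable correlation (default 0.5: the two
factors of the pattern are assumed correlated, and a moderate positive
value is the natural stand-in when no population value is available), then
draws each item response from its graded-response category distribution at
the respondent's severity.  Defaults emulate the validation study the
packaged bank comes from: 344 respondents on the 9-item scale.

Missingness, when requested, is completely at random; it exists to exercise
listwise-deletion code paths, not to model questionnaire drop-out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bank import ItemBank, read_bank, reference_bank, write_bank
from .core import category_prob_table
from .responses import ResponseMatrix, write_response_matrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_theta",
    "simulate_responses",
    "simulate_dataset",
    "make_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_respondents: int = 344
    latent_corr: float = 0.5
    bank: ItemBank | None = None  # None -> packaged reference bank
    link: str | None = None  # None -> the bank's link
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not -1.0 < self.latent_corr < 1.0:
            raise ValueError("latent correlation must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def resolved_bank(self) -> ItemBank:
        bank = self.bank if self.bank is not None else reference_bank()
        if self.link is not None:
            bank = bank.with_link(self.link)
        return bank


@dataclass(frozen=True)
class SimulatedDataset:
    responses: ResponseMatrix
    true_theta: np.ndarray
    bank: ItemBank
    latent_corr: float
    seed: int


def simulate_theta(n: int, latent_corr: float, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n severity vectors from N(0, [[1, r], [r, 1]])."""
    if not -1.0 < latent_corr < 1.0:
        raise ValueError("latent correlation must lie in (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = np.array([[1.0, latent_corr], [latent_corr, 1.0]])
    L = np.linalg.cholesky(R)
    return rng.standard_normal((n, 2)) @ L.T


def simulate_responses(
    theta: np.ndarray,
    bank: ItemBank,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ResponseMatrix:
    """Draw each cell from its item's category distribution at that row's theta."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != bank.n_dim:
        raise ValueError(
            f"theta has {theta.shape[1]} columns but the bank has {bank.n_dim} dimensions"
        )
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = theta.shape[0]
    values = np.empty((n, bank.n_items))
    for j, item in enumerate(bank.items):
        probs = category_prob_table(item, theta)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        values[:, j] = (u[:, None] > cum).sum(axis=1)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
    return ResponseMatrix.from_array(values, item_ids=bank.item_ids)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """One reproducible draw of the whole study: severities plus responses."""
    bank = config.resolved_bank()
    rng = np.random.default_rng(config.seed)
    theta = simulate_theta(config.n_respondents, config.latent_corr, rng)
    responses = simulate_responses(theta, bank, config.missing_rate, rng)
    return SimulatedDataset(
        responses=responses,
        true_theta=theta,
        bank=bank,
        latent_corr=config.latent_corr,
        seed=config.seed,
    )


def make_fixture(config: SimulationConfig, out_dir: str | Path) -> SimulatedDataset:
    """Simulate and write a fixture directory: responses, truth bank,
    true severities and a config manifest, all as delimited/structured text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    write_response_matrix(ds.responses, out / "responses.csv")
    write_bank(ds.bank, out / "truth_bank.yaml")
    np.savetxt(
        out / "true_theta.csv",
        ds.true_theta,
        delimiter=",",
        header=",".join(f"theta{k + 1}" for k in range(ds.true_theta.shape[1])),
        comments="",
    )
    manifest = {
        "n_respondents": config.n_respondents,
        "latent_corr": config.latent_corr,
        "link": ds.bank.link,
        "missing_rate": config.missing_rate,
        "seed": config.seed,
        "n_items": ds.bank.n_items,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return ds
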