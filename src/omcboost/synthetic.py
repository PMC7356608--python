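"""Seeded synthetic pharmacogenomics cases with known ground truth.

The generator emulates the data shapes the pipeline consumes — a cell-line by
feature matrix (Bernoulli mutation indicators for binary profiles, standard
Gaussian intensities for continuous ones) and a log10 IC50 response driven by
a small planted subset of features plus Gaussian noise — so every stage of the
workflow is testable without any external download. Pure-null cases
(``k_true = 0``) give the false-positive controls.

Features are i.i.d.; real omics matrices carry gene-gene correlation that is
deliberately not modeled here, so results on synthetic cases measure the
machinery, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import CaseDataset, Omics

__all__ = ["SyntheticCaseSpec", "GroundTruth", "generate_case", "generate_panel",
           "reference_spec"]

LINKS = ("linear", "threshold", "interaction")

#: Default feature counts per profile type, mirroring typical curated panels
#: (hundreds of cancer genes / informative CpG islands, not whole-genome).
DEFAULT_P = {"binary": 470, "continuous": 450}


@dataclass(frozen=True)
class SyntheticCaseSpec:
    """Parameters of one synthetic case.

    noise_sd is on the log10 IC50 scale; mutation_rate is the per-gene
    Bernoulli rate for binary profiles. ``p = None`` resolves to 470 for
    binary omics and 450 for continuous.
    """

    m: int = 45
    p: int | None = None
    omics: Omics = Omics.GEX
    k_true: int = 5
    effect_sizes: tuple[float, ...] = (1.0, 1.0, 0.8, 0.8, 0.6)
    noise_sd: float = 0.5
    mutation_rate: float = 0.1
    link: str = "linear"
    seed: int = 0
    drug: str = "synthetic-drug"
    cancer_type: str = "SYNTH"

    def __post_init__(self) -> None:
        object.__setattr__(self, "omics", Omics(self.omics))
        if self.k_true < 0 or (self.p is not None and self.k_true > self.p):
            raise ValueError(f"k_true={self.k_true} out of range [0, p]")
        if len(self.effect_sizes) != self.k_true:
            raise ValueError(
                f"{len(self.effect_sizes)} effect sizes for k_true={self.k_true}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in (0, 1)")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}, got {self.link!r}")
        if self.m < 3:
            raise ValueError("m must be >= 3")

    @property
    def resolved_p(self) -> int:
        if self.p is not None:
            return self.p
        return DEFAULT_P[self.omics.ranking_kind]


@dataclass
class GroundTruth:
    """What was planted: the informative features, link, and signal-to-noise."""

    informative_features: list[str]
    effect_sizes: list[float]
    link: str
    noise_sd: float
    signal_to_noise: float


def reference_spec(signal: bool = True, seed: int = 0, **overrides) -> SyntheticCaseSpec:
    """The reference generator used for power / false-positive-rate runs.

    Signal cases: m = 45 (the eligibility floor, training n = 35, k-grid
    2..17), p = 200 continuous features, 5 informative with effect sizes
    (1, 1, 0.8, 0.8, 0.6) and noise_sd = 0.5 on a linear link. Null cases
    differ only in carrying no informative features.
    """
    base = dict(m=45, p=200, omics=Omics.GEX, noise_sd=0.5, link="linear", seed=seed)
    if signal:
        base.update(k_true=5, effect_sizes=(1.0, 1.0, 0.8, 0.8, 0.6))
    else:
        base.update(k_true=0, effect_sizes=())
    base.update(overrides)
    return SyntheticCaseSpec(**base)


def _link_signal(Z: np.ndarray, effects: np.ndarray, link: str) -> np.ndarray:
    """The noiseless response component from the informative columns Z."""
    if Z.shape[1] == 0:
        return np.zeros(Z.shape[0])
    if link == "linear":
        return Z @ effects
    if link == "threshold":
        # Step at each feature's sample median: tree-friendly, non-linear.
        steps = (Z > np.median(Z, axis=0)).astype(float)
        return steps @ effects
    if link == "interaction":
        signal = np.zeros(Z.shape[0])
        if Z.shape[1] >= 2:
            signal += effects[0] * Z[:, 0] * Z[:, 1]
            rest = Z[:, 2:] @ effects[2:] if Z.shape[1] > 2 else 0.0
            signal += rest
        else:
            signal += effects[0] * Z[:, 0]
        return signal
    raise ValueError(f"unknown link {link!r}")


def generate_case(spec: SyntheticCaseSpec) -> tuple[CaseDataset, GroundTruth]:
    """Generate one synthetic case and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    p = spec.resolved_p
    if spec.k_true > p:
        raise ValueError(f"k_true={spec.k_true} exceeds p={p}")
    if spec.omics.is_binary:
        X = rng.binomial(1, spec.mutation_rate, size=(spec.m, p)).astype(float)
    else:
        X = rng.standard_normal((spec.m, p))
    informative = np.sort(rng.choice(p, size=spec.k_true, replace=False))
    effects = np.asarray(spec.effect_sizes, dtype=float)
    signal = _link_signal(X[:, informative], effects, spec.link)
    y = signal + rng.normal(0.0, spec.noise_sd, size=spec.m)

    width = len(str(p))
    feature_names = [f"g{j:0{width}d}" for j in range(p)]
    cell_ids = [f"CL{i:04d}" for i in range(spec.m)]
    dataset = CaseDataset(
        drug=spec.drug,
        cancer_type=spec.cancer_type,
        omics=spec.omics,
        cell_ids=cell_ids,
        feature_names=feature_names,
        X=X,
        y=y,
    )
    signal_var = float(np.var(signal))
    snr = signal_var / spec.noise_sd**2 if spec.noise_sd > 0 else float("inf")
    truth = GroundTruth(
        informative_features=[feature_names[j] for j in informative],
        effect_sizes=list(effects),
        link=spec.link,
        noise_sd=spec.noise_sd,
        signal_to_noise=snr,
    )
    return dataset, truth


def generate_panel(
    n_cases: int,
    spec_template: SyntheticCaseSpec,
    signal_fraction: float,
    seed: int = 0,
) -> list[tuple[CaseDataset, GroundTruth]]:
    """A panel of cases, a known subset of which carries signal.

    Exactly ``round(n_cases * signal_fraction)`` cases keep the template's
    planted features; the rest are pure-null copies (k_true = 0). Which
    positions carry signal is a seeded draw, recorded implicitly by each
    case's ground truth. Drugs are labeled drug-000, drug-001, ...
    """
    if not 0 <= signal_fraction <= 1:
        raise ValueError("signal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_signal = int(round(n_cases * signal_fraction))
    signal_positions = set(rng.choice(n_cases, size=n_signal, replace=False).tolist())
    case_seeds = rng.integers(0, 2**31, size=n_cases)
    panel = []
    for i in range(n_cases):
        spec_i = replace(
            spec_template,
            seed=int(case_seeds[i]),
            drug=f"drug-{i:03d}",
        )
        if i not in signal_positions:
            spec_i = replace(spec_i, k_true=0, effect_sizes=())
        panel.append(generate_case(spec_i))
    return panel
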