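"""Synthetic paired expression studies with known ground truth.

The generator emulates a matched-pairs microarray design: each subject
contributes one normal and one tumour sample, measured on the log2 scale.
Three structural ingredients are planted on top of independent Gaussian
noise:

* a per-(feature, subject) random effect shared by the two tissues of a
  pair, which induces the within-pair correlation a paired design relies
  on while leaving distinct features independent;
* differential expression: selected features receive a fixed tumour-minus-
  normal log2 shift with a known sign;
* correlation modules: each module has one latent Gaussian factor per
  sample, and its members load on that factor with a loading calibrated so
  the within-stratum Pearson correlation between two direct-sign members
  equals ``rho_target`` (Spearman ≈ Pearson under Gaussianity).

Defaults mirror a small two-cohort pancreatic study: 9 matched pairs,
~1105 miRNA features, noise SD 0.3 on the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirnet.io import ExpressionStudy, read_study, write_study


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``sign_pattern`` controls member loadings on the shared latent factor:
    ``direct`` gives all-positive loadings (all pairwise correlations
    ≈ +rho_target); ``inverse`` alternates loading signs so adjacent
    members anti-correlate (with >2 members not every pair can be
    negative); ``mixed`` draws signs at random.
    """

    size: int
    rho_target: float
    sign_pattern: str = "direct"

    def validate(self) -> None:
        if self.size < 2:
            raise ConfigError(f"module size must be ≥ 2, got {self.size}")
        if not 0.0 < self.rho_target < 1.0:
            raise ConfigError(
                f"rho_target must lie strictly inside (0,1), got "
                f"{self.rho_target}")
        if self.sign_pattern not in ("direct", "inverse", "mixed"):
            raise ConfigError(
                f"unknown sign_pattern {self.sign_pattern!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic paired study.

    ``subject_sd`` defaults to ``noise_sd`` when None, matching the
    convention that the between-subject spread is on the order of the
    residual noise.
    """

    n_pairs: int = 9
    n_features: int = 1105
    n_de: int = 0
    de_log2fc_range: tuple[float, float] = (1.0, 2.0)
    modules: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 0.3
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    subject_sd: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError(f"n_pairs must be positive, got {self.n_pairs}")
        if self.n_features < 1:
            raise ConfigError(
                f"n_features must be positive, got {self.n_features}")
        if not 0 <= self.n_de <= self.n_features:
            raise ConfigError(
                f"n_de must satisfy 0 ≤ n_de ≤ n_features "
                f"({self.n_de} vs {self.n_features})")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.subject_sd is not None and self.subject_sd < 0:
            raise ConfigError("subject_sd must be non-negative")
        lo, hi = self.de_log2fc_range
        if lo < 0 or hi < lo:
            raise ConfigError(
                f"de_log2fc_range must be 0 ≤ lo ≤ hi, got {self.de_log2fc_range}")
        for m in self.modules:
            m.validate()
        if sum(m.size for m in self.modules) > self.n_features:
            raise ConfigError("sum of module sizes exceeds n_features")

    @property
    def effective_subject_sd(self) -> float:
        return self.noise_sd if self.subject_sd is None else self.subject_sd


@dataclass
class GroundTruth:
    """Planted truth of a simulated study.

    ``de_log2fc`` maps each planted differentially expressed miRNA id to
    its true signed tumour-minus-normal log2 shift; ``module_assignments``
    maps each feature id to its module label or ``"background"``.
    """

    de_log2fc: dict[str, float] = field(default_factory=dict)
    module_assignments: dict[str, str] = field(default_factory=dict)

    @property
    def de_features(self) -> set[str]:
        return set(self.de_log2fc)

    def module_members(self, module_id: str) -> set[str]:
        return {f for f, m in self.module_assignments.items()
                if m == module_id}

    @property
    def module_ids(self) -> list[str]:
        ids = {m for m in self.module_assignments.values()
               if m != "background"}
        return sorted(ids)


def _module_loading(rho: float, subject_sd: float, noise_sd: float) -> float:
    # Pearson corr between two same-sign members is a² / (a² + s² + n²);
    # solve for the loading a.
    resid = subject_sd ** 2 + noise_sd ** 2
    return math.sqrt(rho * resid / (1.0 - rho))


def simulate_study(
        config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate a paired study and its ground truth.

    The output is deterministic given ``config.seed``: identical configs
    yield bit-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_feat, n_pairs = config.n_features, config.n_pairs
    subject_sd = config.effective_subject_sd

    width = max(4, len(str(n_feat)))
    features = [f"sim-miR-{i + 1:0{width}d}" for i in range(n_feat)]
    subjects = [f"S{j + 1:03d}" for j in range(n_pairs)]
    sample_ids, subj_col, tissue_col = [], [], []
    for subj in subjects:
        for tissue, suffix in (("normal", "N"), ("tumour", "T")):
            sample_ids.append(f"{subj}_{suffix}")
            subj_col.append(subj)
            tissue_col.append(tissue)
    n_samples = 2 * n_pairs

    baseline = rng.uniform(*config.baseline_mean_range, size=n_feat)

    # planted DE: random features, random sign, |log2FC| uniform in range
    de_idx = rng.choice(n_feat, size=config.n_de, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=config.n_de)
    de_mag = rng.uniform(*config.de_log2fc_range, size=config.n_de)
    shift = np.zeros(n_feat)
    shift[de_idx] = de_sign * de_mag

    # disjoint module memberships among features, drawn without replacement
    loadings = np.zeros(n_feat)
    assignments = {f: "background" for f in features}
    remaining = rng.permutation(n_feat)
    cursor = 0
    module_members: list[np.ndarray] = []
    for k, mod in enumerate(config.modules):
        members = remaining[cursor:cursor + mod.size]
        cursor += mod.size
        module_members.append(members)
        a = _module_loading(mod.rho_target, subject_sd, config.noise_sd)
        if mod.sign_pattern == "direct":
            signs = np.ones(mod.size)
        elif mod.sign_pattern == "inverse":
            signs = np.where(np.arange(mod.size) % 2 == 0, 1.0, -1.0)
        else:
            signs = rng.choice([-1.0, 1.0], size=mod.size)
        loadings[members] = a * signs
        for i in members:
            assignments[features[i]] = f"M{k + 1}"

    subject_effect = rng.normal(0.0, subject_sd, size=(n_feat, n_pairs))
    noise = rng.normal(0.0, config.noise_sd, size=(n_feat, n_samples))
    factors = rng.standard_normal((len(config.modules), n_samples))

    values = np.empty((n_feat, n_samples))
    tumour_mask = np.array([t == "tumour" for t in tissue_col])
    pair_of_sample = np.repeat(np.arange(n_pairs), 2)
    values[:] = baseline[:, None]
    values += subject_effect[:, pair_of_sample]
    values[:, tumour_mask] += shift[:, None]
    values += noise
    for k, members in enumerate(module_members):
        values[members, :] += loadings[members, None] * factors[k][None, :]

    study = ExpressionStudy(
        pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                     columns=sample_ids),
        pd.DataFrame({"subject_id": subj_col, "tissue": tissue_col,
                      "cohort": ["SIM"] * n_samples},
                     index=pd.Index(sample_ids, name="sample_id")))
    truth = GroundTruth(
        de_log2fc={features[i]: float(shift[i]) for i in sorted(de_idx)},
        module_assignments=assignments)
    return study, truth


def write_fixture(study: ExpressionStudy, truth: GroundTruth,
                  directory: str | Path) -> dict[str, Path]:
    """Write matrix/sample-sheet/ground-truth TSVs that round-trip through
    :mod:`mirnet.io`. Returns the paths written, keyed by role."""
    if len(study.features) == 0:
        raise ValueError("refusing to write a fixture with no features")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "ground_truth.tsv",
    }
    write_study(study, paths["matrix"], paths["samples"])
    rows = [(f, truth.de_log2fc.get(f, 0.0),
             truth.module_assignments.get(f, "background"))
            for f in study.features]
    pd.DataFrame(rows, columns=["feature_id", "true_log2fc", "module_id"]
                 ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read the ground-truth TSV written by :func:`write_fixture`."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"feature_id": str})
    de = {r.feature_id: float(r.true_log2fc)
          for r in df.itertuples() if r.true_log2fc != 0.0}
    modules = {r.feature_id: str(r.module_id) for r in df.itertuples()}
    return GroundTruth(de, modules)


def read_fixture(directory: str | Path
                 ) -> tuple[ExpressionStudy, GroundTruth]:
    directory = Path(directory)
    study = read_study(directory / "matrix.tsv", directory / "samples.tsv")
    return study, read_ground_truth(directory / "ground_truth.tsv")
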