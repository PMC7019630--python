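"""Synthetic serum amino-acid cohorts with a planted two-class structure.

The generator emulates a case/control targeted-metabolomics study: a panel
of 37 serum amino acids and derivatives (µmol/L) measured in 66 frail or
pre-frail older adults with type 2 diabetes (cases) and 30 robust,
non-diabetic controls.  Nine analytes carry a genuine class effect, each
drawn per class from a normal distribution with the published
class-conditional mean and standard deviation; the remaining 28 analytes
have identical parameters in both classes and act as a null background.

Concentrations are non-negative by construction: draws are taken from a
normal truncated at zero (rejection-resampling), with the latent location
calibrated so that the truncated distribution has exactly the template
mean.  Analytes are sampled independently — the templates specify only
marginal moments — though :func:`generate` accepts any template, so a
correlated panel can be emulated by post-processing if needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

CASE = 1
CONTROL = 0
CLASS_TOKENS = {"case": CASE, "control": CONTROL}
_TOKEN_OF = {CASE: "case", CONTROL: "control"}


class TemplateError(ValueError):
    """Invalid analyte or clinical template."""


class MalformedTableError(ValueError):
    """CSV table lacks required columns or has an unparseable layout."""


class MissingValueError(ValueError):
    """CSV table contains an empty cell; no silent imputation is performed."""


class NonNumericValueError(ValueError):
    """A concentration cell could not be parsed as a number."""


class UnknownClassError(ValueError):
    """A class label token other than 'case'/'control' was encountered."""


@dataclass(frozen=True)
class AnalyteTemplate:
    """Class-conditional marginal moments for one analyte (µmol/L)."""

    name: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    discriminant: bool = False

    def __post_init__(self) -> None:
        for label, value in (
            ("case_mean", self.case_mean),
            ("case_sd", self.case_sd),
            ("control_mean", self.control_mean),
            ("control_sd", self.control_sd),
        ):
            if not np.isfinite(value) or value <= 0:
                raise TemplateError(
                    f"analyte {self.name!r}: {label} must be positive, got {value!r}"
                )


# Discriminant analytes: published case/control means ± SDs (µmol/L).
_DISCRIMINANT_PANEL: tuple[tuple[str, float, float, float, float], ...] = (
    ("3-methylhistidine", 7.8, 4.2, 5.2, 2.5),
    ("Alanine", 542.3, 165.8, 384.3, 98.3),
    ("Arginine", 168.3, 91.2, 103.7, 31.2),
    ("Ethanolamine", 11.5, 3.4, 9.0, 2.2),
    ("Glutamic acid", 130.0, 66.8, 54.3, 21.3),
    ("Ornithine", 103.2, 37.6, 109.4, 25.0),
    ("Sarcosine", 2.5, 0.9, 1.6, 0.6),
    ("Taurine", 100.4, 49.0, 189.5, 47.2),
    ("Tryptophan", 66.2, 23.4, 62.0, 13.1),
)

# Null background: 28 analytes with no class effect.  The identities of the
# non-discriminant panel members were not published, so these are placeholder
# parameters at typical fasting-serum magnitudes; override via a template
# file for a different panel.
_NULL_PANEL: tuple[tuple[str, float, float], ...] = (
    ("Glycine", 245.0, 65.0),
    ("Serine", 115.0, 28.0),
    ("Proline", 185.0, 60.0),
    ("Valine", 230.0, 55.0),
    ("Leucine", 135.0, 35.0),
    ("Isoleucine", 65.0, 20.0),
    ("Threonine", 125.0, 35.0),
    ("Methionine", 25.0, 7.0),
    ("Phenylalanine", 62.0, 14.0),
    ("Tyrosine", 63.0, 18.0),
    ("Lysine", 175.0, 40.0),
    ("Histidine", 80.0, 16.0),
    ("Asparagine", 50.0, 12.0),
    ("Aspartic acid", 18.0, 8.0),
    ("Glutamine", 570.0, 110.0),
    ("Cystine", 45.0, 15.0),
    ("Citrulline", 38.0, 12.0),
    ("1-methylhistidine", 6.5, 3.5),
    ("Hydroxyproline", 14.0, 6.0),
    ("Carnosine", 1.2, 0.5),
    ("Anserine", 0.9, 0.4),
    ("Cystathionine", 0.35, 0.15),
    ("alpha-Aminobutyric acid", 22.0, 7.0),
    ("beta-Alanine", 3.1, 1.2),
    ("beta-Aminoisobutyric acid", 2.0, 1.0),
    ("gamma-Aminobutyric acid", 0.25, 0.1),
    ("Phosphoethanolamine", 1.8, 0.8),
    ("Phosphoserine", 7.5, 2.5),
)


def default_template() -> list[AnalyteTemplate]:
    """Return the default 37-analyte panel template.

    Nine analytes carry the published class-conditional parameters and are
    flagged ``discriminant``; 28 null analytes share parameters across
    classes.
    """
    panel = [
        AnalyteTemplate(name, cm, cs, km, ks, discriminant=True)
        for name, cm, cs, km, ks in _DISCRIMINANT_PANEL
    ]
    panel.extend(
        AnalyteTemplate(name, m, s, m, s, discriminant=False)
        for name, m, s in _NULL_PANEL
    )
    return panel


@dataclass
class Dataset:
    """A sample-by-analyte concentration matrix with binary class labels.

    ``y`` codes cases as 1 and controls as 0 throughout the package.
    """

    sample_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    analyte_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.y) != n:
            raise ValueError("sample_ids, X and y must agree in length")
        if len(self.analyte_names) != p:
            raise ValueError("analyte_names must match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.analyte_names)
        frame.insert(0, "class", [_TOKEN_OF[v] for v in self.y])
        frame.insert(0, "sample_id", self.sample_ids)
        return frame


@lru_cache(maxsize=512)
def _truncated_location(mean: float, sd: float) -> float:
    """Latent normal location whose zero-truncated mean equals ``mean``.

    For a normal N(mu, sd) truncated to [0, inf) the mean exceeds mu by
    sd * phi(-mu/sd) / Phi(mu/sd); this solves for mu so the truncated draw
    is calibrated exactly to the template mean.  When the truncation mass
    is negligible (mu/sd > 8) the correction is below machine precision and
    the template mean is returned unchanged.
    """
    if mean / sd > 8.0:
        return mean

    def gap(mu: float) -> float:
        a = -mu / sd
        # mean of N(mu, sd) conditioned on being >= 0
        return mu + sd * norm.pdf(a) / norm.sf(a) - mean

    # gap(mean) > 0 always; for mu far below zero the truncated mean -> 0+.
    lo = mean - 20.0 * sd
    return float(optimize.brentq(gap, lo, mean, xtol=1e-12 * max(1.0, mean)))


def _draw_nonnegative(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Zero-truncated normal draws with mean calibrated to ``mean``."""
    mu = _truncated_location(mean, sd)
    out = rng.normal(mu, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
        bad = out < 0
    return out


def _validate_sizes(n_case: int, n_control: int) -> None:
    if n_case < 2 or n_control < 2:
        raise ValueError("each class needs at least 2 samples")


def generate(
    template: list[AnalyteTemplate],
    n_case: int = 66,
    n_control: int = 30,
    seed: int | np.random.SeedSequence | None = None,
    ) -> Dataset:
    """Simulate one cohort from a panel template.

    Each analyte is drawn independently per class from a zero-truncated
    normal with the template's class-conditional parameters.  Cases occupy
    the first ``n_case`` rows (label 1).  Deterministic given ``seed``.
    """
    if not template:
        raise TemplateError("empty analyte template")
    _validate_sizes(n_case, n_control)
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    X = np.empty((n, len(template)))
    for j, analyte in enumerate(template):
        X[:n_case, j] = _draw_nonnegative(rng, analyte.case_mean, analyte.case_sd, n_case)
        X[n_case:, j] = _draw_nonnegative(
            rng, analyte.control_mean, analyte.control_sd, n_control
        )
    y = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    ids = [f"case_{i + 1:03d}" for i in range(n_case)] + [
        f"control_{i + 1:03d}" for i in range(n_control)
    ]
    return Dataset(ids, X, y, [a.name for a in template])


def generate_null(
    template: list[AnalyteTemplate],
    n_case: int = 66,
    n_control: int = 30,
    seed: int | np.random.SeedSequence | None = None,
) -> Dataset:
    """Simulate a negative-control cohort with no class effect.

    Both arms are drawn from the control-class parameters of every analyte;
    the labels keep the requested case/control split.  Useful as a null
    input for the validation machinery.
    """
    nulled = [
        replace(a, case_mean=a.control_mean, case_sd=a.control_sd)
        for a in template
    ]
    return generate(nulled, n_case, n_control, seed)


@dataclass(frozen=True)
class ClinicalArm:
    """Per-class clinical covariate moments."""

    age_mean: float
    age_sd: float
    female_fraction: float
    bmi_mean: float
    bmi_sd: float
    sppb_mean: float
    sppb_sd: float
    disease_count_mean: float
    disease_count_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise TemplateError("female_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ClinicalTemplate:
    case: ClinicalArm
    control: ClinicalArm


def default_clinical_template() -> ClinicalTemplate:
    """Published cohort characteristics: age, sex, BMI, SPPB, disease count."""
    return ClinicalTemplate(
        case=ClinicalArm(76.5, 14.5, 32 / 66, 29.2, 4.9, 8.6, 2.9, 2.8, 1.0),
        control=ClinicalArm(74.6, 4.3, 16 / 30, 26.7, 2.4, 11.3, 0.9, 2.9, 2.0),
    )


def generate_clinical(
    clinical_template: ClinicalTemplate | None = None,
    n_case: int = 66,
    n_control: int = 30,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Simulate a clinical covariate table matched to a generated cohort.

    Continuous covariates are normal per class; SPPB is rounded to an
    integer and clamped to its 0-12 range; sex is a per-class Bernoulli
    draw on the female fraction.
    """
    if clinical_template is None:
        clinical_template = default_clinical_template()
    _validate_sizes(n_case, n_control)
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    for arm, n, token in (
        (clinical_template.case, n_case, "case"),
        (clinical_template.control, n_control, "control"),
    ):
        age = rng.normal(arm.age_mean, arm.age_sd, n)
        female = rng.random(n) < arm.female_fraction
        bmi = rng.normal(arm.bmi_mean, arm.bmi_sd, n)
        sppb = np.clip(np.rint(rng.normal(arm.sppb_mean, arm.sppb_sd, n)), 0, 12)
        disease = rng.normal(arm.disease_count_mean, arm.disease_count_sd, n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{token}_{i + 1:03d}",
                    "class": token,
                    "age": age[i],
                    "sex": "female" if female[i] else "male",
                    "bmi": bmi[i],
                    "sppb": int(sppb[i]),
                    "disease_count": disease[i],
                }
            )
    return pd.DataFrame(rows)


def write_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as UTF-8 CSV: sample_id, class, then one analyte column each."""
    dataset.to_frame().to_csv(path, index=False)


def read_csv(path: str | Path) -> Dataset:
    """Read a sample-by-analyte CSV written by :func:`write_csv`.

    Raises
    ------
    MalformedTableError
        if the ``sample_id`` or ``class`` column is absent.
    UnknownClassError
        if a class token other than ``case``/``control`` appears.
    MissingValueError
        if any concentration cell is empty (no silent imputation).
    NonNumericValueError
        if a concentration cell cannot be parsed as a number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for required in ("sample_id", "class"):
        if required not in frame.columns:
            raise MalformedTableError(
                f"missing required column {required!r} in {path}"
            )
    analyte_names = [c for c in frame.columns if c not in ("sample_id", "class")]
    if not analyte_names:
        raise MalformedTableError(f"no analyte columns found in {path}")

    tokens = frame["class"].tolist()
    for token in tokens:
        if token not in CLASS_TOKENS:
            raise UnknownClassError(f"unknown class token {token!r} in {path}")
    y = np.array([CLASS_TOKENS[t] for t in tokens], dtype=int)

    X = np.empty((len(frame), len(analyte_names)))
    for j, name in enumerate(analyte_names):
        for i, cell in enumerate(frame[name].tolist()):
            if cell.strip() == "":
                raise MissingValueError(
                    f"missing value for analyte {name!r}, row {i + 1} in {path}"
                )
            try:
                X[i, j] = float(cell)
            except ValueError as exc:
                raise NonNumericValueError(
                    f"non-numeric cell {cell!r} for analyte {name!r}, row {i + 1}"
                ) from exc
    if len(np.unique(y)) < 2:
        raise UnknownClassError("label column must contain both classes")
    return Dataset(frame["sample_id"].tolist(), X, y, analyte_names)


def write_template_csv(template: list[AnalyteTemplate], path: str | Path) -> None:
    """Write a panel template as CSV (analyte, case/control moments, flag)."""
    pd.DataFrame(
        {
            "analyte": [a.name for a in template],
            "case_mean": [a.case_mean for a in template],
            "case_sd": [a.case_sd for a in template],
            "control_mean": [a.control_mean for a in template],
            "control_sd": [a.control_sd for a in template],
            "discriminant": [int(a.discriminant) for a in template],
        }
    ).to_csv(path, index=False)


def read_template_csv(path: str | Path) -> list[AnalyteTemplate]:
    """Read a panel template CSV written by :func:`write_template_csv`."""
    frame = pd.read_csv(path)
    required = {"analyte", "case_mean", "case_sd", "control_mean", "control_sd"}
    missing = required - set(frame.columns)
    if missing:
        raise MalformedTableError(f"template file missing columns: {sorted(missing)}")
    disc = (
        frame["discriminant"].astype(bool)
        if "discriminant" in frame.columns
        else pd.Series(False, index=frame.index)
    )
    return [
        AnalyteTemplate(
            str(row["analyte"]),
            float(row["case_mean"]),
            float(row["case_sd"]),
            float(row["control_mean"]),
            float(row["control_sd"]),
            bool(disc.iloc[i]),
        )
        for i, (_, row) in enumerate(frame.iterrows())
    ]
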