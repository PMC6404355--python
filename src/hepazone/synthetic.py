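"""Seeded synthetic-data generators calibrated to the published ground truth.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the estimators assume: 4PL-shaped viability tables with
replicate noise at the assay-anchored IC50s, channel dye images rendered from
the gradient solver, Ct tables encoding the CHIR -> CYP fold inductions
against the 18S reference, and log2 expression matrices with a known spiked
differential set.  Generators are pure functions of (preset, arguments,
seed): the same call with the same seed is bit-identical.

Ground truth lives in a versioned YAML registry shipped as package data
(:func:`load_presets`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import diffusion, zonal
from .dose_response import (
    CONDITION_CHIR9,
    CONDITION_UNTREATED,
    InductionCurve,
    fourpl,
    induction_at,
)
from .errors import InvalidParameterError
from .expression import GROUP_CONTROL, GROUP_TREATED
from .imaging import ChannelImage

DEFAULT_SEED = 0

_Z975 = 1.959963984540054

__all__ = [
    "DEFAULT_SEED",
    "DrugPreset",
    "Presets",
    "load_presets",
    "resolve_qpcr_preset",
    "gen_dose_response",
    "gen_qpcr_ct",
    "gen_expression_matrix",
    "gen_channel_images",
    "gen_zonal_screen",
    "ScreenExperiment",
]


@dataclass(frozen=True)
class DrugPreset:
    """Ground-truth 4PL parameters for one drug at both CHIR conditions."""

    drug: str
    unit: str
    hill: float
    top: float
    bottom: float
    assay_top_dose: float
    screen_top_dose: "float | None"
    ic50_untreated: float
    ci95_untreated: "tuple[float, float]"
    ic50_chir9: float
    ci95_chir9: "tuple[float, float]"

    def ic50(self, condition: str) -> float:
        if condition == CONDITION_UNTREATED:
            return self.ic50_untreated
        if condition == CONDITION_CHIR9:
            return self.ic50_chir9
        raise InvalidParameterError(f"unknown condition {condition!r}")

    def log_ic50_se(self, condition: str) -> float:
        """SE of log10 IC50 back-computed from the printed 95% CI.

        The CI is taken as symmetric on the linear scale; the half-width over
        the normal 97.5% quantile gives a linear-scale SE, converted to the
        log10 scale by the delta method.
        """
        ic = self.ic50(condition)
        lo, hi = (
            self.ci95_untreated if condition == CONDITION_UNTREATED else self.ci95_chir9
        )
        se_lin = (hi - lo) / 2.0 / _Z975
        return se_lin / (ic * math.log(10.0))

    def zonal_params(self) -> zonal.DrugZonalParams:
        return zonal.DrugZonalParams(
            self.drug,
            self.unit,
            self.ic50_untreated,
            self.ic50_chir9,
            self.log_ic50_se(CONDITION_UNTREATED),
            self.log_ic50_se(CONDITION_CHIR9),
            self.hill,
            self.top,
            self.bottom,
        )


_DRUG_ALIASES = {"apap": "acetaminophen", "chir": None}


class Presets:
    """Accessor over the YAML preset registry."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.version = raw.get("version")
        self.noise = raw["noise"]
        self.gradient = raw["gradient"]
        self.qpcr = raw["qpcr"]
        self.damage = raw["damage"]
        self.screen = raw["screen"]
        self.image = raw["image"]

    def drug_names(self) -> "list[str]":
        return list(self.raw["drugs"])

    def drug(self, name: str) -> DrugPreset:
        key = _DRUG_ALIASES.get(name.lower(), name.lower()) or name.lower()
        if key not in self.raw["drugs"]:
            raise InvalidParameterError(f"unknown drug preset {name!r}")
        d = self.raw["drugs"][key]
        return DrugPreset(
            key,
            d["unit"],
            float(d["hill"]),
            float(d["top"]),
            float(d["bottom"]),
            float(d["assay_top_dose"]),
            None if d["screen_top_dose"] is None else float(d["screen_top_dose"]),
            float(d["ic50"]["untreated"]["value"]),
            tuple(d["ic50"]["untreated"]["ci95"]),
            float(d["ic50"]["CHIR_9uM"]["value"]),
            tuple(d["ic50"]["CHIR_9uM"]["ci95"]),
        )

    def induction_curve(self, cyp: str) -> InductionCurve:
        table = self.raw["induction"]
        match = {k.upper(): k for k in table}.get(cyp.upper())
        if match is None:
            raise InvalidParameterError(f"unknown CYP {cyp!r}")
        points = tuple(sorted((float(c), float(f)) for c, f in table[match].items()))
        return InductionCurve(match, points)

    def geometry(self, n_grid: int = 901) -> diffusion.ChannelGeometry:
        ch = self.raw["channel"]
        return diffusion.ChannelGeometry(ch["length_cm"], ch["diameter_cm"], n_grid)

    def boundary_conditions(self) -> diffusion.BoundaryConditions:
        ch = self.raw["channel"]
        return diffusion.BoundaryConditions(ch["inlet1_uM"], ch["inlet2_uM"])

    def day7_profile(self, n_grid: int = 901) -> diffusion.ConcentrationProfile:
        """The canonical near-linear gradient used by the generators."""
        return diffusion.solve_profile(
            self.geometry(n_grid),
            self.boundary_conditions(),
            float(self.gradient["D_eff_cm2_s"]),
            float(self.gradient["time_days"]) * diffusion.DAY_S,
        )


def load_presets() -> Presets:
    """Load the packaged preset registry."""
    text = resources.files("hepazone").joinpath("data/presets.yaml").read_text()
    return Presets(yaml.safe_load(text))


def _dilution_series(top_dose: float, n_doses: int) -> np.ndarray:
    return top_dose / 2.0 ** np.arange(n_doses, dtype=float)


def _viability_noise(rng: np.random.Generator, truth: np.ndarray, sd: float) -> np.ndarray:
    v = truth + rng.normal(0.0, sd, size=truth.shape) if sd > 0 else truth.copy()
    return np.clip(v, 0.0, None)


def gen_dose_response(
    drug: str,
    condition: str,
    n_doses: int = 8,
    n_reps: int = 6,
    seed: int = DEFAULT_SEED,
    noise_sd: "float | None" = None,
    presets: "Presets | None" = None,
) -> pd.DataFrame:
    """Synthetic CCK-8 viability table for one drug and CHIR condition.

    Doses are ``n_doses`` two-fold dilutions from the assay top dose plus
    dose-0 control wells; viabilities are the preset 4PL plus Gaussian noise
    (default sd 5% points), clipped at 0.
    """
    presets = presets or load_presets()
    p = presets.drug(drug)
    sd = presets.noise["viability_sd_pct"] if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    doses = np.concatenate([[0.0], _dilution_series(p.assay_top_dose, n_doses)])
    dose_col = np.repeat(doses, n_reps)
    truth = fourpl(dose_col, p.top, p.bottom, p.ic50(condition), p.hill)
    viab = _viability_noise(rng, truth, sd)
    return pd.DataFrame(
        {
            "drug": p.drug,
            "condition": condition,
            "dose": dose_col,
            "unit": p.unit,
            "replicate": np.tile(np.arange(1, n_reps + 1), doses.size),
            "viability_pct": viab,
        }
    )


_QPCR_PRESETS = {
    "cyp1a2_chir9": ("CYP1A2", 9.0),
    "cyp2e1_chir9": ("CYP2E1", 9.0),
    "cyp3a4_chir9": ("CYP3A4", 9.0),
    "cyp2b6_chir9": ("CYP2B6", 9.0),
}


def resolve_qpcr_preset(name: str) -> "tuple[str, float]":
    """Map a qPCR preset name to (CYP isoform, CHIR uM)."""
    key = name.lower()
    if key not in _QPCR_PRESETS:
        raise InvalidParameterError(f"unknown qPCR preset {name!r}")
    return _QPCR_PRESETS[key]


def gen_qpcr_ct(
    cyp: str,
    chir: float = 9.0,
    n_reps: int = 3,
    seed: int = DEFAULT_SEED,
    ct_sd: "float | None" = None,
    presets: "Presets | None" = None,
) -> pd.DataFrame:
    """Synthetic Ct table (control + treated) encoding the CHIR fold induction.

    The 18S reference sits at a fixed Ct, the untreated target at a baseline
    Ct, and CHIR treatment lowers the target Ct by log2(fold) cycles; all Ct
    values carry Gaussian noise (default sd 0.2 cycles).  Recovery with the
    2^-ddCt estimator at the default noise carries a ~+-20% fold tolerance
    band (propagating sd 0.2 through four Ct means of three replicates).
    """
    presets = presets or load_presets()
    curve = presets.induction_curve(cyp)
    fold = induction_at(curve, chir)
    sd = presets.noise["ct_sd_cycles"] if ct_sd is None else ct_sd
    ref_gene = presets.qpcr["reference_gene"]
    ref_ct = float(presets.qpcr["reference_ct"])
    base_ct = float(presets.qpcr["baseline_ct"])
    rng = np.random.default_rng(seed)
    rows = []
    for group, target_ct in (
        (GROUP_CONTROL, base_ct),
        (GROUP_TREATED, base_ct - math.log2(fold)),
    ):
        for r in range(1, n_reps + 1):
            sample = f"{group}_{r}"
            rows.append((sample, group, curve.cyp, target_ct + rng.normal(0.0, sd)))
            rows.append((sample, group, ref_gene, ref_ct + rng.normal(0.0, sd)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


def gen_expression_matrix(
    n_genes: int = 10_000,
    n_deg: int = 300,
    log2fc: float = 1.5,
    sd: float = 0.3,
    n_per_group: int = 4,
    seed: int = DEFAULT_SEED,
) -> "tuple[pd.DataFrame, np.ndarray, pd.Index]":
    """Log2 expression matrix with a spiked differential set.

    Returns (matrix genes x samples, group labels, index of true DEGs).
    Spiked genes are shifted by ``+- log2fc`` in the treated group with
    random sign.
    """
    if n_deg > n_genes:
        raise InvalidParameterError("n_deg must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    base = rng.normal(8.0, 1.0, size=n_genes)
    control = base[:, None] + rng.normal(0.0, sd, size=(n_genes, n_per_group))
    treated = base[:, None] + rng.normal(0.0, sd, size=(n_genes, n_per_group))
    deg_pos = rng.choice(n_genes, size=n_deg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_deg)
    treated[deg_pos] += (signs * log2fc)[:, None]
    cols = [f"ctrl_{i+1}" for i in range(n_per_group)] + [
        f"trt_{i+1}" for i in range(n_per_group)
    ]
    mat = pd.DataFrame(np.hstack([control, treated]), index=genes, columns=cols)
    groups = np.array([GROUP_CONTROL] * n_per_group + [GROUP_TREATED] * n_per_group)
    return mat, groups, genes[np.sort(deg_pos)]


def _damage_profile(
    p: DrugPreset, dose: float, chir: np.ndarray, damage_slope: float
) -> np.ndarray:
    """Damage fraction per axial position: 1 - V/top with the local IC50."""
    ic = zonal.local_ic50(p.zonal_params(), chir)
    viab = p.bottom + (p.top - p.bottom) / (1.0 + (dose / ic) ** p.hill)
    return np.clip(damage_slope * (1.0 - viab / p.top), 0.0, 1.0)


def gen_channel_images(
    drug: str = "acetaminophen",
    dose: float = 10.0,
    seed: int = DEFAULT_SEED,
    time: "float | None" = None,
    damage_slope: "float | None" = None,
    presets: "Presets | None" = None,
) -> "dict[str, ChannelImage]":
    """Render the three-dye channel image triple from the gradient solver.

    * ``chir_uv``: the solver profile at ``time`` (default: the preset day-7
      gradient) as column intensity, relative to the source concentration;
    * ``celltracker``: spatially uniform cell signal with multiplicative
      speckle, since cells are dispersed uniformly along the channel;
    * ``ethd1``: CellTracker signal scaled by the local damage fraction from
      the drug's 4PL with the section-local IC50 rule.

    All three share geometry, mask, and additive Gaussian noise with sd equal
    to ``image_noise_frac`` of the dynamic range.
    """
    presets = presets or load_presets()
    p = presets.drug(drug)
    img_cfg = presets.image
    n_rows, n_cols = int(img_cfg["n_rows"]), int(img_cfg["n_cols"])
    r0, r1 = img_cfg["mask_rows"]
    bg = float(img_cfg["background"])
    amp = float(img_cfg["amplitude"])
    noise_sd = presets.noise["image_noise_frac"] * amp
    slope = float(presets.damage["slope"]) if damage_slope is None else damage_slope

    geom = presets.geometry(n_grid=n_cols)
    bc = presets.boundary_conditions()
    t = float(presets.gradient["time_days"]) * diffusion.DAY_S if time is None else time
    profile = diffusion.solve_profile(geom, bc, float(presets.gradient["D_eff_cm2_s"]), t)
    rel = profile.concentrations / max(bc.c_inlet2, 1e-12)
    chir_local = profile.concentrations

    pixel_size = geom.length / (n_cols - 1)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    mask[r0:r1, :] = True
    rng = np.random.default_rng(seed)

    def _render(signal_cols: np.ndarray, speckle: bool) -> np.ndarray:
        img = np.full((n_rows, n_cols), bg)
        field = np.tile(signal_cols, (n_rows, 1))
        if speckle:
            field = field * rng.gamma(25.0, 1.0 / 25.0, size=field.shape)
        img = img + np.where(mask, field, 0.0)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        return np.clip(img, 0.0, None)

    damage = _damage_profile(p, dose, chir_local, slope)
    ct_cols = np.full(n_cols, 0.6 * amp)
    images = {
        "chir_uv": ChannelImage(_render(rel * amp, False), "chir_uv", pixel_size, mask),
        "celltracker": ChannelImage(
            _render(ct_cols, True), "celltracker", pixel_size, mask
        ),
        "ethd1": ChannelImage(
            _render(damage * ct_cols, True), "ethd1", pixel_size, mask
        ),
    }
    return images


@dataclass
class ScreenExperiment:
    """A synthetic six-section screening run for one drug."""

    drug: str
    unit: str
    sections: "list[zonal.ZonalSection]"
    doses: np.ndarray
    tables: "list[pd.DataFrame]"  # one viability table per section
    truth: zonal.DrugZonalParams


def gen_zonal_screen(
    drug: str,
    seed: int = DEFAULT_SEED,
    n_sections: "int | None" = None,
    n_doses: "int | None" = None,
    n_reps: "int | None" = None,
    noise_sd: "float | None" = None,
    top_dose: "float | None" = None,
    presets: "Presets | None" = None,
) -> ScreenExperiment:
    """Generate a full zonal screening experiment along the day-7 gradient.

    The channel is sectioned, each section's mean CHIR sets its local IC50,
    and noisy CCK-8 viabilities are drawn for two-fold dilutions of the
    screen top dose (plus dose-0 controls).  Drugs without a preset screen
    range (isoniazid was never screened in the channel) need an explicit
    ``top_dose``.
    """
    presets = presets or load_presets()
    p = presets.drug(drug)
    if top_dose is None:
        top_dose = p.screen_top_dose
    if top_dose is None:
        raise InvalidParameterError(
            f"{p.drug} has no screen dose range; pass top_dose explicitly"
        )
    n_sections = int(presets.screen["n_sections"]) if n_sections is None else n_sections
    n_doses = int(presets.screen["n_doses"]) if n_doses is None else n_doses
    n_reps = int(presets.screen["n_reps"]) if n_reps is None else n_reps
    sd = presets.noise["viability_sd_pct"] if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    profile = presets.day7_profile()
    sections = zonal.section_channel(profile, n_sections, allow_custom=True)
    doses = np.concatenate([[0.0], _dilution_series(top_dose, n_doses)])
    params = p.zonal_params()
    tables = []
    for sec in sections:
        ic = zonal.local_ic50(params, sec.mean_chir)
        dose_col = np.repeat(doses, n_reps)
        truth = fourpl(dose_col, p.top, p.bottom, ic, p.hill)
        viab = _viability_noise(rng, truth, sd)
        tables.append(
            pd.DataFrame(
                {
                    "drug": p.drug,
                    "condition": f"section_{sec.index}",
                    "dose": dose_col,
                    "unit": p.unit,
                    "replicate": np.tile(np.arange(1, n_reps + 1), doses.size),
                    "viability_pct": viab,
                }
            )
        )
    return ScreenExperiment(p.drug, p.unit, sections, doses, tables, params)
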