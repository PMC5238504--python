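"""Synthetic radioligand experiments with known ground truth.

Emulates the assay design used for muscarinic receptor kinetics in CHO
cell membranes: saturation binding of [3H]NMS (32 pM - 1 nM, triplicate
wells, nonspecific binding defined by 1 uM atropine) and dissociation
time courses started from pre-equilibrated tracer by adding unlabelled
competitor at 10 uM - 10 mM (duplicate wells), with several independent
experiments summarized as means +/- SEM.

Ground-truth presets (:data:`TABLE_PRESETS`) carry the published binding
constants of the wild-type M1-M5 subtypes and of the M2/M3 extracellular
loop mutants, so every downstream fitting stage can be exercised, and its
recovery quantified, without any laboratory data.

Noise model: multiplicative Gaussian on the bound signal (scintillation
counting error grows with signal), truncated at zero; default CV 3%.
Nonspecific binding is linear in tracer concentration and is *not*
subtracted here — subtraction happens in the fitting module, as in the
assay workflow.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tandemsite.errors import ValidationError
from tandemsite.kinetic_model import (
    Phase,
    Protocol,
    RateSet,
    equilibrium_state,
    simulate,
)

_NMS_TRACER_GRID = tuple(np.geomspace(32e-12, 1e-9, 8))
_COMPETITOR_GRID = tuple(np.geomspace(10e-6, 10e-3, 7))


@dataclass(frozen=True)
class GroundTruth:
    """True binding parameters used to generate synthetic data.

    pK values are -log10 molar; rates are per minute.  ``k_0`` (the
    competitor-free dissociation rate entering the retardation curve)
    defaults to ``k_off``.  ``biphasic`` truth is expressed through
    ``k_off2``/``f`` (percent of sites dissociating at ``k_off2``).
    """

    pK_D: float
    k_off: float
    pK_A: float
    B_MAX: float = 1000.0
    nH: float = 1.0
    k_0: float | None = None
    k_off2: float | None = None
    f: float | None = None

    def __post_init__(self) -> None:
        if self.k_off <= 0:
            raise ValidationError("k_off must be > 0")
        if self.nH <= 0:
            raise ValidationError("nH must be > 0")
        if self.f is not None and not (0.0 <= self.f <= 100.0):
            raise ValidationError("f must lie in [0, 100]")
        if self.B_MAX <= 0:
            raise ValidationError("B_MAX must be > 0")

    @property
    def K_D(self) -> float:
        return 10.0 ** -self.pK_D

    @property
    def K_A(self) -> float:
        return 10.0 ** -self.pK_A

    @property
    def k_0_effective(self) -> float:
        return self.k_off if self.k_0 is None else self.k_0

    def k_obs(self, competitor_conc: float) -> float:
        """Expected observed dissociation rate at competitor level X."""
        x = competitor_conc
        return self.k_0_effective / (1.0 + (x / self.K_A) ** self.nH)


@dataclass(frozen=True)
class AssayDesign:
    """Replicate structure, concentration grids and noise level."""

    n_experiments: int = 4
    n_wells_kinetic: int = 2
    n_wells_saturation: int = 3
    tracer_concs: tuple = _NMS_TRACER_GRID
    competitor_concs: tuple = _COMPETITOR_GRID
    time_points: tuple | None = None   # None: adaptive 9-point grid per curve
    n_time_points: int = 9
    half_lives: float = 3.0            # span of the adaptive time grid
    include_zero_competitor: bool = True
    noise_cv: float = 0.03
    nonspecific_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValidationError("n_experiments must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if not self.tracer_concs or any(c <= 0 for c in self.tracer_concs):
            raise ValidationError("tracer concentrations must be > 0")
        if not self.competitor_concs or any(c <= 0
                                            for c in self.competitor_concs):
            raise ValidationError("competitor concentrations must be > 0")


def _experiment_rngs(design: AssayDesign) -> list[np.random.Generator]:
    """One reproducible substream per independent experiment."""
    ss = np.random.SeedSequence(design.rng_seed)
    return [np.random.default_rng(child)
            for child in ss.spawn(design.n_experiments)]


def _noisy(values: np.ndarray, cv: float,
           rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise, truncated at zero."""
    if cv == 0:
        return np.asarray(values, dtype=float)
    factors = 1.0 + cv * rng.standard_normal(np.shape(values))
    return np.maximum(np.asarray(values, dtype=float) * factors, 0.0)


# ---------------------------------------------------------------------------
# saturation


def gen_saturation(truth: GroundTruth, design: AssayDesign) -> pd.DataFrame:
    """Generate saturation binding wells (total + nonspecific).

    Specific binding follows the one-site isotherm
    B_MAX * X / (K_D + X); the nonspecific component is linear in tracer
    concentration, scaled so it equals ``nonspecific_fraction`` of total
    binding at X = K_D.  Total and nonspecific wells receive independent
    noise, as they are separate wells in the assay.
    """
    kd, bmax = truth.K_D, truth.B_MAX
    nf = design.nonspecific_fraction
    # NS(K_D) = nf * total(K_D) with total = Bmax/2 + NS(K_D)
    ns_slope = (nf / (1.0 - nf)) * (bmax / 2.0) / kd if nf > 0 else 0.0
    rows = []
    for exp_i, rng in enumerate(_experiment_rngs(design)):
        for x in design.tracer_concs:
            spec = bmax * x / (kd + x)
            ns = ns_slope * x
            for well in range(design.n_wells_saturation):
                rows.append({
                    "experiment_id": exp_i,
                    "conc_tracer_M": x,
                    "replicate": well,
                    "total_binding": float(_noisy(spec + ns,
                                                  design.noise_cv, rng)),
                    "nonspecific_binding": float(_noisy(ns, design.noise_cv,
                                                        rng)),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dissociation


def _time_grid(design: AssayDesign, k_obs: float) -> np.ndarray:
    if design.time_points is not None:
        return np.asarray(design.time_points, dtype=float)
    t_max = design.half_lives * math.log(2.0) / max(k_obs, 1e-9)
    return np.linspace(0.0, t_max, design.n_time_points)


def _closed_form_decay(truth: GroundTruth, t: np.ndarray, x: float) -> np.ndarray:
    if truth.k_off2 is not None and truth.f is not None and x == 0.0:
        f = truth.f
        return (100.0 - f) * np.exp(-truth.k_off * t) + f * np.exp(
            -truth.k_off2 * t)
    return 100.0 * np.exp(-truth.k_obs(x) * t)


def fast_exchange_rateset(truth: GroundTruth,
                          vestibule_exchange: float = 1e4,
                          k_in_ratio: float = 100.0) -> RateSet:
    """Mechanistic rates consistent with a ground truth, fast-exchange regime.

    Builds a :class:`RateSet` whose competitor-free observed dissociation
    rate equals ``k_0`` and whose vestibule blocking constant equals
    ``K_A``, with vestibule exchange and competitor binding much faster
    than translocation so the retardation closed form applies.
    """
    k0 = truth.k_0_effective
    # two-step egress: k_obs0 = k_out * k_off_vest / (k_off_vest + k_in)
    k_off_vest = vestibule_exchange * k0
    k_in = k_off_vest / k_in_ratio
    k_out = k0 * (k_off_vest + k_in) / k_off_vest
    k_iso = k_out / k_in
    # choose k_on_vest so the apparent K_D matches the truth
    k_on_vest = k_off_vest * k_iso / (truth.K_D * (1.0 + k_iso))
    k_off_block = vestibule_exchange * k0
    k_on_block = k_off_block / truth.K_A
    return RateSet(k_on_vest=k_on_vest, k_off_vest=k_off_vest, k_in=k_in,
                   k_out=k_out, k_on_block=k_on_block,
                   k_off_block=k_off_block, leak=0.0)


def _mechanistic_decay(scheme: RateSet, t: np.ndarray, x: float,
                       tracer_preequil: float = 1e-9) -> np.ndarray:
    y0 = equilibrium_state(scheme, tracer_preequil, 0.0)
    duration = float(t.max()) if t.max() > 0 else 1.0
    phase = Phase(duration=duration, tracer_conc=0.0, competitor_conc=x,
                  sampling_times=t)
    tc = simulate(scheme, Protocol([phase]), receptor_total=1e-10,
                  initial_state=y0)
    bound = tc.set_index("time_min")["bound_pct"].reindex(t).to_numpy()
    return 100.0 * bound / bound[0]


def gen_dissociation_series(truth: GroundTruth, design: AssayDesign,
                            mode: str = "closed_form",
                            scheme: RateSet | None = None) -> pd.DataFrame:
    """Generate dissociation time courses across competitor concentrations.

    For every independent experiment and competitor concentration X
    (optionally including a competitor-free control), the expected decay
    is Y(t) = 100 * exp(-k_obs(X) * t) with
    k_obs(X) = k_0 / (1 + (X / K_A)**nH) in ``closed_form`` mode, or the
    simulated tandem-scheme decay in ``mechanistic`` mode (``scheme``
    required).  Each well receives independent multiplicative noise; the
    time grid is adaptive per concentration, spanning
    ``design.half_lives`` half-lives of the expected rate with
    ``design.n_time_points`` points, unless ``design.time_points`` pins a
    fixed grid.
    """
    if mode not in ("closed_form", "mechanistic"):
        raise ValidationError("mode must be 'closed_form' or 'mechanistic'")
    if mode == "mechanistic" and scheme is None:
        raise ValidationError("mechanistic mode requires a RateSet")
    concs = list(design.competitor_concs)
    if design.include_zero_competitor:
        concs = [0.0] + concs
    rows = []
    mech_cache: dict[float, np.ndarray] = {}
    for exp_i, rng in enumerate(_experiment_rngs(design)):
        for x in concs:
            t = _time_grid(design, truth.k_obs(x))
            if mode == "closed_form":
                expect = _closed_form_decay(truth, t, x)
            else:
                if x not in mech_cache:
                    mech_cache[x] = _mechanistic_decay(scheme, t, x)
                expect = mech_cache[x]
            for well in range(design.n_wells_kinetic):
                y = _noisy(expect, design.noise_cv, rng)
                for ti, yi in zip(t, y):
                    rows.append({
                        "experiment_id": exp_i,
                        "conc_tracer_M": 1e-9,
                        "conc_competitor_M": x,
                        "time_min": ti,
                        "replicate": well,
                        "bound_pct": yi,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published ground-truth presets
#
# Wild-type subtypes (NMS tracer): pK_D / k_off [1/min] / pK_A, with the
# slope factor nH = 1.5 for the steep M2 and M5 retardation curves.
# Mutant families: M3 ECL3-loop swaps and M2 vestibule point mutants.

TABLE_PRESETS: dict[str, GroundTruth] = {
    # subtype survey (NMS)
    "M1_wt": GroundTruth(pK_D=9.60, k_off=0.056, pK_A=3.52),
    "M2_wt": GroundTruth(pK_D=9.43, k_off=0.27, pK_A=3.62, nH=1.5),
    "M3_wt": GroundTruth(pK_D=9.64, k_off=0.034, pK_A=3.25),
    "M4_wt": GroundTruth(pK_D=9.66, k_off=0.043, pK_A=3.31),
    "M5_wt": GroundTruth(pK_D=9.52, k_off=0.0162, pK_A=3.86, nH=1.5),
    # M3 ECL3 loop mutants
    "M3_S_to_P": GroundTruth(pK_D=9.65, k_off=0.057, pK_A=3.25),
    "M3_K_to_N": GroundTruth(pK_D=9.63, k_off=0.097, pK_A=3.52),
    "M3_KFN_to_NVT": GroundTruth(pK_D=9.55, k_off=0.26, pK_A=3.65),
    "M3_DKFN_to_ANVT": GroundTruth(pK_D=9.56, k_off=0.21, pK_A=3.64),
    "M3_SK_to_PN": GroundTruth(pK_D=9.63, k_off=0.12, pK_A=3.55),
    "M3_SKFN_to_PNVT": GroundTruth(pK_D=9.48, k_off=0.25, pK_A=3.65),
    "M3_DSKFN_to_APNVT": GroundTruth(pK_D=9.45, k_off=0.26, pK_A=3.66),
    # M2 vestibule point mutants
    "M2_D97N": GroundTruth(pK_D=9.03, k_off=0.42, pK_A=3.24),
    "M2_D97A": GroundTruth(pK_D=9.04, k_off=0.41, pK_A=3.23),
    "M2_E172A": GroundTruth(pK_D=9.21, k_off=0.45, pK_A=3.39),
    "M2_E175A": GroundTruth(pK_D=9.19, k_off=0.44, pK_A=3.40),
    "M2_Y177A": GroundTruth(pK_D=9.44, k_off=0.27, pK_A=3.63),
    "M2_N419A": GroundTruth(pK_D=8.95, k_off=0.78, pK_A=3.11),
}

_TABLE_OF = {name: (1 if name.endswith("_wt") and name[1] in "12345"
                    else 2 if name.startswith("M3_") else 3)
             for name in TABLE_PRESETS}


def _fixture_seed(base_seed: int, name: str, kind: str) -> int:
    digest = hashlib.sha256(f"{name}:{kind}".encode()).digest()
    return (base_seed + int.from_bytes(digest[:4], "big")) % (2 ** 31)


def write_fixture_suite(output_dir, base_seed: int = 0,
                        design: AssayDesign | None = None) -> pd.DataFrame:
    """Write CSV fixtures for every ground-truth preset, plus a manifest.

    For each preset a dissociation series and a saturation curve are
    generated with a fixed, name-derived seed and written as CSV; the
    YAML manifest maps each fixture file to its ground truth.  Re-running
    with the same ``base_seed`` reproduces the files byte for byte.
    Returns the manifest as a DataFrame.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        base = design or AssayDesign()
        manifest = []
        for name, truth in TABLE_PRESETS.items():
            entry = {"name": name, "table": _TABLE_OF[name],
                     "truth": {"pK_D": truth.pK_D, "k_off": truth.k_off,
                               "pK_A": truth.pK_A, "nH": truth.nH,
                               "B_MAX": truth.B_MAX}}
            for kind, gen in (("dissociation", gen_dissociation_series),
                              ("saturation", gen_saturation)):
                seed = _fixture_seed(base_seed, name, kind)
                df = gen(truth, replace(base, rng_seed=seed))
                path = out / f"{name}_{kind}.csv"
                df.to_csv(path, index=False, float_format="%.10g")
                entry[f"{kind}_file"] = path.name
                entry[f"{kind}_seed"] = seed
            manifest.append(entry)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"base_seed": base_seed, "fixtures": manifest},
                           fh, sort_keys=True)
    except OSError as exc:
        raise ValidationError(f"cannot write fixture suite: {exc}") from exc
    return pd.DataFrame([{
        "name": m["name"], "table": m["table"],
        "dissociation_file": m["dissociation_file"],
        "saturation_file": m["saturation_file"],
        **{f"truth_{k}": v for k, v in m["truth"].items()},
    } for m in manifest])
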