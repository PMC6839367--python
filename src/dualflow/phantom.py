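"""Seeded digital dual-supply DCE-MRI phantom.

Generates the full measurement chain the real protocols produce: ground
truth kinetic parameters per tumor region, analytic dual AIFs carried by
"vessel" voxels, tissue concentration curves through the forward kinetic
operator, SPGR dynamic signal at the acquisition settings, a multi-flip-
angle precontrast stack from the assigned native T1 values, and additive
Gaussian signal noise.  Everything is bit-reproducible from (config,
seed).

Two protocols are provided, mirroring the study conditions: a lung-tumor
protocol at 2 s temporal resolution with 130 frames, and a pleural
protocol at 5 s frames over the same acquisition window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aif import AIFModelParams, DualInputSpec, evaluate_aif
from .kinetics import (
    KineticFitParams,
    PhysioConstants,
    TissueCurveEngine,
    derive_parameters,
)
from .signal_model import AcquisitionParams, T1MapVoxel, concentration_to_signal, spgr_signal

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "Phantom",
    "generate_phantom",
    "truth_table",
    "default_pulmonary_aif",
    "default_systemic_aif",
]

# region label codes in the label volume
BACKGROUND, TUMOR_A, TUMOR_B, VESSEL_PA, VESSEL_AO = 0, 1, 2, 3, 4


def default_pulmonary_aif() -> AIFModelParams:
    """Pulmonary-artery AIF: earlier onset, higher peak (~5.7 mM)."""
    return AIFModelParams(a_b=220.0, mu_b=15.0, a_g=1.2, mu_g=0.18,
                         t_onset=0.40, tau_rc=0.22, kappa_rc=0.35)


def default_systemic_aif() -> AIFModelParams:
    """Aortic AIF: delayed onset, dispersed (broader, lower) first pass,
    matching late washout.

    The aortic bolus has traversed the pulmonary capillary bed and the
    left heart, so its first pass is substantially broader and lower
    than the pulmonary-arterial one (indicator-dilution dispersion); the
    washout phases of the two sites equilibrate.
    """
    return AIFModelParams(a_b=95.0, mu_b=8.0, a_g=1.15, mu_g=0.18,
                         t_onset=0.47, tau_rc=0.25, kappa_rc=0.30)


def _default_regions() -> dict:
    # two tumor regions with distinct pulmonary flow fractions; scales
    # chosen in the regime of voxelwise 2CX estimates in dual-supply
    # thoracic tumors (BF tens of mL/min/100 g, gamma well inside (0, 1))
    return {
        TUMOR_A: KineticFitParams(model="2CX", f_over_vp=5.0, ps_over_vp=1.0,
                                  v_p=0.1, v_i=0.3, t_lag=0.05, gamma=0.8),
        TUMOR_B: KineticFitParams(model="2CX", f_over_vp=3.0, ps_over_vp=1.5,
                                  v_p=0.08, v_i=0.35, t_lag=0.08, gamma=0.3),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom layout, protocol and noise settings.

    noise_sd is the Gaussian signal noise standard deviation as a
    fraction of the peak dynamic signal (0.05 corresponds to SNR 20 at
    the enhancement peak).
    """

    protocol: str = "nsclc"  # {"nsclc": 2 s x 130 frames, "mpm": 5 s frames}
    shape: tuple = (8, 8, 1)
    regions: dict = field(default_factory=_default_regions)
    pulmonary_aif: AIFModelParams = field(default_factory=default_pulmonary_aif)
    systemic_aif: AIFModelParams = field(default_factory=default_systemic_aif)
    noise_sd: float = 0.05
    #: noise of the precontrast multi-FA volumes relative to the dynamic
    #: frames; the FA scans are unhurried 3D acquisitions with several-fold
    #: better SNR than a 2-s dynamic frame
    vfa_noise_scale: float = 1.0 / 3.0
    seed: int = 0
    h_lv: float = 0.45
    t1_native_ms: dict = field(
        default_factory=lambda: {TUMOR_A: 1200.0, TUMOR_B: 1100.0,
                                 VESSEL_PA: 1600.0, VESSEL_AO: 1600.0,
                                 BACKGROUND: 900.0}
    )
    m0: float = 1000.0

    def __post_init__(self):
        if self.protocol not in ("nsclc", "mpm"):
            raise ValueError("protocol must be 'nsclc' or 'mpm'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.shape) != 3 or self.shape[0] < 3 or self.shape[1] < 2:
            raise ValueError("shape must be 3-D with at least 3x2 in-plane")
        for lbl, p in self.regions.items():
            if not isinstance(p, KineticFitParams):
                raise ValueError(f"region {lbl} truth must be KineticFitParams")

    def acquisition(self) -> AcquisitionParams:
        if self.protocol == "nsclc":
            return AcquisitionParams(frame_interval=2.0, n_frames=130)
        # same acquisition window at 5 s frames
        return AcquisitionParams(frame_interval=5.0, n_frames=52)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a generated phantom; regenerable from (config, seed)."""

    config: PhantomConfig
    labels: np.ndarray  # region label volume
    params_by_label: dict  # label -> KineticFitParams
    inputs: DualInputSpec

    def params_at(self, idx) -> KineticFitParams | None:
        lbl = int(self.labels[tuple(idx)])
        return self.params_by_label.get(lbl)


@dataclass(frozen=True)
class Phantom:
    """Generated phantom: dynamic signal, multi-FA stack, masks, truth."""

    signal_4d: np.ndarray  # spatial + (n_frames,)
    vfa_stack: np.ndarray  # spatial + (n_fa,)
    conc_4d: np.ndarray  # noiseless concentration, spatial + (n_frames,)
    labels: np.ndarray
    truth: PhantomTruth
    acq: AcquisitionParams

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.labels, (TUMOR_A, TUMOR_B))

    @property
    def times_min(self) -> np.ndarray:
        return self.acq.times_min

    def vessel_curve(self, label: int) -> np.ndarray:
        """Mean noiseless blood concentration over a vessel region."""
        m = self.labels == label
        return self.conc_4d[m].mean(axis=0)


def _layout_labels(shape) -> np.ndarray:
    """Region layout: one full row per vessel ROI (pulmonary trunk and
    aorta are large structures), tumor below, split into the two
    gamma regions left/right."""
    labels = np.full(shape, BACKGROUND, dtype=int)
    nx, ny, nz = shape
    labels[0, :, :] = VESSEL_PA
    labels[1, :, :] = VESSEL_AO
    half = ny // 2
    labels[2:, :half, :] = TUMOR_A
    labels[2:, half:, :] = TUMOR_B
    return labels


def generate_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Generate the phantom for ``config`` (deterministic given its seed)."""
    config = config or PhantomConfig()
    acq = config.acquisition()
    t = acq.times_min
    labels = _layout_labels(config.shape)
    inputs = DualInputSpec(mode="dual", pulmonary=config.pulmonary_aif,
                           systemic=config.systemic_aif, h_lv=config.h_lv)
    engine = TissueCurveEngine(inputs, t, dt=1e-3)

    conc = np.zeros(config.shape + (acq.n_frames,))
    for lbl, params in config.regions.items():
        curve = engine.evaluate(params.model, params)
        conc[labels == lbl] = curve
    # vessel voxels carry the whole-blood AIF curves themselves
    conc[labels == VESSEL_PA] = evaluate_aif(config.pulmonary_aif, t)
    conc[labels == VESSEL_AO] = evaluate_aif(config.systemic_aif, t)

    signal = np.zeros_like(conc)
    n_fa = len(acq.flip_angles)
    vfa = np.zeros(config.shape + (n_fa,))
    for lbl, t1 in config.t1_native_ms.items():
        m = labels == lbl
        if not m.any():
            continue
        vox = T1MapVoxel(t1_native=t1, m0=config.m0)
        signal[m] = concentration_to_signal(conc[m], vox, acq)
        vfa[m] = spgr_signal(t1, np.asarray(acq.flip_angles), acq.tr, config.m0)

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        # noise referenced to the peak tumor signal *enhancement*: at
        # noise_sd = 0.05 the dynamic range that carries the kinetic
        # information has SNR ~ 20, mirroring the convention of quoting
        # concentration noise as a fraction of the curve peak (blood-pool
        # voxels, which enhance more, sit at higher SNR, as in real data)
        tumor = np.isin(labels, (TUMOR_A, TUMOR_B))
        if tumor.any():
            dyn = signal[tumor]
            ref = float((dyn - dyn[:, :1]).max())
        else:
            ref = float(signal.max())
        signal = signal + rng.normal(0.0, config.noise_sd * ref, signal.shape)
        vfa = vfa + rng.normal(
            0.0, config.noise_sd * config.vfa_noise_scale * ref, vfa.shape)

    truth = PhantomTruth(config=config, labels=labels,
                         params_by_label=dict(config.regions), inputs=inputs)
    return Phantom(signal_4d=signal, vfa_stack=vfa, conc_4d=conc,
                   labels=labels, truth=truth, acq=acq)


def truth_table(truth: PhantomTruth,
                consts: PhysioConstants = PhysioConstants()) -> pd.DataFrame:
    """Flat per-region table of truth fitting and derived parameters."""
    rows = []
    for lbl, p in sorted(truth.params_by_label.items()):
        d = derive_parameters(p, consts)
        row = {"label": lbl, "model": p.model}
        row.update({k: v for k, v in p.as_dict().items() if k != "model"})
        row.update(d.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
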