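"""Built-in example datasets.

Two classic human brain/kidney qPCR experiments (c-myc target, GAPDH
reference) ship with the package:

* :func:`ct1` — six replicates per tissue measured in separate tubes;
  used for relative quantification.
* :func:`ct3` — a seven-point serial-dilution experiment in triplicate;
  used for standard curves and the amplification-efficiency check.
  Only per-dilution means and SDs were published for this experiment, so
  the replicate level is reconstructed deterministically (synthetic): the
  triple ``{mean − sd, mean, mean + sd}`` has exactly the published mean
  and sample SD, and balanced symmetric replicates leave every
  least-squares fit identical to a fit on the means.
* :func:`ct4_like` — a synthetic stand-in for a 24+24-sample
  treated/control plant experiment (MT7 target, ubiquitin reference)
  whose replicate values were never published; generated with a known
  ΔΔCT of −0.68 cycles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import CtTable

__all__ = ["ct1", "ct3", "ct4_like", "dilution_amounts", "table1_summary"]

# Brain then kidney, six replicates each.  The verbatim kidney GAPDH
# series ends in 24.18, which is inconsistent with its published summary
# (mean 22.66, SD 0.08): no six-replicate sample containing 24.18 can
# have that mean and SD.  The corrected series replaces it with 22.76,
# the unique value (to 2 decimals) reproducing both — see docs/methods.md.
_CT1_CMYC = [30.72, 30.34, 30.58, 30.34, 30.50, 30.43,
             27.06, 27.03, 27.03, 27.10, 26.99, 26.94]
_CT1_GAPDH = [23.70, 23.56, 23.47, 23.65, 23.69, 23.68,
              22.76, 22.61, 22.62, 22.60, 22.61, 22.76]
_CT1_GAPDH_VERBATIM = _CT1_GAPDH[:-1] + [24.18]
_CT1_GROUPS = ["brain"] * 6 + ["kidney"] * 6

# Published per-dilution summaries of the dilution series (mean ± SD),
# input amounts in ng.  The final dilution completes the monotone
# two-fold/2.5-fold series 1, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01.
_DILUTION_AMOUNTS = np.array([1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01])
_CT3_CMYC_MEAN = np.array([25.59, 26.77, 28.14, 29.18, 30.14, 31.44, 32.42])
_CT3_CMYC_SD = np.array([0.04, 0.09, 0.05, 0.13, 0.03, 0.16, 0.12])
_CT3_GAPDH_MEAN = np.array([22.64, 23.73, 25.12, 26.16, 27.17, 28.62, 29.45])
_CT3_GAPDH_SD = np.array([0.03, 0.05, 0.10, 0.02, 0.06, 0.10, 0.08])


def ct1(corrected: bool = True) -> CtTable:
    """Brain/kidney c-myc + GAPDH CTs, 6 separate-tube replicates per tissue.

    ``corrected=False`` returns the verbatim published replicates,
    including the inconsistent kidney GAPDH value 24.18.
    """
    gapdh = _CT1_GAPDH if corrected else _CT1_GAPDH_VERBATIM
    df = pd.DataFrame({"c_myc": _CT1_CMYC, "GAPDH": gapdh})
    return CtTable(df, group=np.array(_CT1_GROUPS, dtype=object))


def dilution_amounts(replicates: int = 3) -> np.ndarray:
    """Per-row input amounts (ng) of the dilution experiment."""
    return np.repeat(_DILUTION_AMOUNTS, replicates)


def table1_summary() -> pd.DataFrame:
    """Published per-dilution mean ± SD summaries of the ct3 experiment."""
    return pd.DataFrame(
        {
            "amount": _DILUTION_AMOUNTS,
            "c_myc_mean": _CT3_CMYC_MEAN,
            "c_myc_sd": _CT3_CMYC_SD,
            "GAPDH_mean": _CT3_GAPDH_MEAN,
            "GAPDH_sd": _CT3_GAPDH_SD,
        }
    )


def _triples(mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return np.stack([mean - sd, mean, mean + sd], axis=1).ravel()


def ct3() -> CtTable:
    """Seven-dilution triplicate series for c-myc and GAPDH (synthetic
    replicate reconstruction constrained to the published summaries)."""
    df = pd.DataFrame(
        {
            "c_myc": _triples(_CT3_CMYC_MEAN, _CT3_CMYC_SD),
            "GAPDH": _triples(_CT3_GAPDH_MEAN, _CT3_GAPDH_SD),
        }
    )
    return CtTable(df, amount=dilution_amounts())


def ct4_like(
    seed: int = 7,
    n_per_group: int = 24,
    delta_ct_control: float = 5.2,
    delta_delta_ct: float = -0.68,
    noise_sd: float = 0.4,
) -> CtTable:
    """Synthetic 24+24 treated/control two-gene experiment.

    Emulates a large control-vs-treatment design with per-row
    ΔCT ~ Normal(5.2, 0.4) in controls and a true ΔΔCT of −0.68 cycles
    (up-regulation of the target in treatment).  Both genes amplify with
    perfect efficiency 2; CT noise is split equally between the two genes
    so the paired ΔCT has the stated SD.
    """
    from .synthetic import GeneratorSpec, GeneSpec, GroupSpec, generate_group_experiment

    m = -1.0 / np.log10(2.0)
    b_target, b_ref = 30.0, 22.0
    # choose target amounts so the noiseless delta CTs match
    amt_ctrl = 10.0 ** ((delta_ct_control - (b_target - b_ref)) / m)
    amt_trt = amt_ctrl * 2.0 ** (-delta_delta_ct)
    spec = GeneratorSpec(
        genes=[GeneSpec("target", 2.0, b_target), GeneSpec("ref", 2.0, b_ref)],
        groups=[
            GroupSpec("control", n_per_group, {"target": amt_ctrl, "ref": 1.0}),
            GroupSpec("treatment", n_per_group, {"target": amt_trt, "ref": 1.0}),
        ],
        noise_sd=noise_sd / np.sqrt(2.0),
        seed=seed,
    )
    return generate_group_experiment(spec)
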