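"""Synthetic cohort ground truth: per-subject physiology and effect sizes.

Samples the scalar truth underlying each synthetic subject — demographics,
heart rate, FRC, tidal volume, and the target mean/dispersion of the SV and
perfusion fields — for a study with a never-vaping control cohort imaged
once and a vaping cohort imaged pre and post exposure.  Defaults emulate
the observed cohort: 6 controls and 14 vapers; mean SV near 0.15 (controls)
and 0.20 (vapers); mean perfusion near 1.4-1.5 mL/min/mL; a heart-rate rise
of about +3 bpm after vaping; and a negative BMI-dependent change in
perfusion (higher BMI, smaller or negative change), with the slope set so
the population BMI vs dQ correlation is about -0.7.

These rows parameterise the imaging phantoms and also support fast
replicate studies of the statistics layer without simulating images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CohortParams", "sample_cohort_truth"]


@dataclass(frozen=True)
class CohortParams:
    """Population parameters of the synthetic study."""

    n_controls: int = 6
    n_vapers: int = 14
    # specific ventilation (dimensionless): mean (between-subject SD)
    sv_mean_control: float = 0.15
    sv_sd_control: float = 0.05
    sv_mean_vaper: float = 0.20
    sv_sd_vaper: float = 0.07
    sv_post_shift: float = 0.01
    sv_post_noise_sd: float = 0.03
    sv_rd_mean: float = 0.31          # within-image heterogeneity target
    sv_rd_sd: float = 0.10
    # perfusion, mL/min/mL
    q_mean_control: float = 1.40
    q_sd_control: float = 0.60
    q_mean_vaper: float = 1.46
    q_sd_vaper: float = 0.76
    q_rd_mean: float = 0.60
    q_rd_sd: float = 0.12
    # BMI-dependent perfusion change after exposure
    bmi_dq_slope: float = -0.06       # mL/min/mL per kg/m^2, centred on mean BMI
    dq_noise_sd: float = 0.25
    # heart rate, bpm
    hr_mean: float = 68.1
    hr_sd: float = 10.5
    hr_post_increase: float = 3.2
    hr_post_noise_sd: float = 4.0
    # demographics and lung volumes
    bmi_mean: float = 24.6
    bmi_sd: float = 4.0
    age_mean: float = 26.4
    age_sd: float = 8.0
    frc_mean: float = 3.0             # L
    frc_sd: float = 0.5
    vt_mean_vaper: float = 1.3        # L
    vt_sd_vaper: float = 0.4
    vt_mean_control: float = 0.7
    vt_sd_control: float = 0.2


def _clip_normal(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def sample_cohort_truth(params: CohortParams | None = None, seed: int = 0) -> pd.DataFrame:
    """One tidy row per subject per timepoint (controls: 'single'; vapers:
    'pre' and 'post') carrying demographics and the ground-truth imaging
    targets used to build each subject's phantom."""
    p = params or CohortParams()
    if p.n_controls < 1 or p.n_vapers < 1:
        raise ValueError("both cohorts need at least one subject")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def base_subject(idx: int, group: str) -> dict:
        return {
            "subject": f"{group[0].upper()}{idx:02d}",
            "group": group,
            "sex": rng.choice(["male", "female"]),
            "age": float(_clip_normal(rng, p.age_mean, p.age_sd, 18, 50)),
            "bmi": float(_clip_normal(rng, p.bmi_mean, p.bmi_sd, 17.0, 36.0)),
            "frc": float(_clip_normal(rng, p.frc_mean, p.frc_sd, 2.0, 4.5)),
        }

    for i in range(p.n_controls):
        s = base_subject(i + 1, "control")
        s.update(
            timepoint="single",
            tidal_volume=float(_clip_normal(rng, p.vt_mean_control, p.vt_sd_control, 0.3, 2.5)),
            heart_rate=float(_clip_normal(rng, p.hr_mean, p.hr_sd, 45, 110)),
            nicotine=np.nan,
            nicotine_type=None,
            pack_years=0.0,
            mean_sv_true=float(_clip_normal(rng, p.sv_mean_control, p.sv_sd_control, 0.06, 0.45)),
            rd_sv_true=float(_clip_normal(rng, p.sv_rd_mean, p.sv_rd_sd, 0.10, 0.6)),
            mean_q_true=float(_clip_normal(rng, p.q_mean_control, p.q_sd_control, 0.6, 3.2)),
            rd_q_true=float(_clip_normal(rng, p.q_rd_mean, p.q_rd_sd, 0.3, 0.9)),
        )
        rows.append(s)

    for i in range(p.n_vapers):
        s = base_subject(i + 1, "vaper")
        vt = float(_clip_normal(rng, p.vt_mean_vaper, p.vt_sd_vaper, 0.3, 2.5))
        hr_pre = float(_clip_normal(rng, p.hr_mean, p.hr_sd, 45, 110))
        hr_post = float(np.clip(hr_pre + rng.normal(p.hr_post_increase, p.hr_post_noise_sd), 45, 120))
        nicotine = float(rng.choice([6.0, 12.0, 18.0, 24.0, 35.0, 50.0]))
        nicotine_type = str(rng.choice(["freebase", "salt"]))
        pack_years = float(rng.uniform(1.5, 10.0)) if rng.random() < 0.5 else 0.0
        sv_pre = float(_clip_normal(rng, p.sv_mean_vaper, p.sv_sd_vaper, 0.06, 0.45))
        sv_post = float(np.clip(sv_pre + rng.normal(p.sv_post_shift, p.sv_post_noise_sd), 0.06, 0.5))
        q_pre = float(_clip_normal(rng, p.q_mean_vaper, p.q_sd_vaper, 0.6, 3.2))
        dq = float(p.bmi_dq_slope * (s["bmi"] - p.bmi_mean) + rng.normal(0.0, p.dq_noise_sd))
        q_post = float(np.clip(q_pre + dq, 0.3, 3.5))
        rd_sv = float(_clip_normal(rng, p.sv_rd_mean, p.sv_rd_sd, 0.10, 0.6))
        rd_q = float(_clip_normal(rng, p.q_rd_mean, p.q_rd_sd, 0.3, 0.9))
        common = dict(
            s,
            tidal_volume=vt,
            nicotine=nicotine,
            nicotine_type=nicotine_type,
            pack_years=pack_years,
        )
        rows.append(dict(common, timepoint="pre", heart_rate=hr_pre,
                         mean_sv_true=sv_pre, rd_sv_true=rd_sv,
                         mean_q_true=q_pre, rd_q_true=rd_q))
        rows.append(dict(common, timepoint="post", heart_rate=hr_post,
                         mean_sv_true=sv_post, rd_sv_true=rd_sv,
                         mean_q_true=q_post, rd_q_true=rd_q))

    df = pd.DataFrame(rows)
    df["nicotine_group"] = np.where(df["nicotine"].isna(), None,
                                    np.where(df["nicotine"] <= 20.0, "low", "high"))
    df["bmi_group"] = np.where(df["bmi"] <= 25.0, "low", "high")
    return df
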