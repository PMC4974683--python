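"""End-to-end orchestration of the 27-case bifurcation study.

``run_study`` walks the full study grid (geometry -> flow conditions ->
flow fields -> probe metrics -> statistics) and assembles the per-case
results table plus the derived statistics: per-angle quadratic dP_SB-Q_SB
fits for the severe (80 %) side-branch stenosis cases, the FFR-vs-angle
difference table, and the dP_SB-vs-helicity regression.

Field sources:

* ``"table3"``  - the packaged published per-case results (no fields built);
* ``"synthetic"`` - calibrated stenotic fixture fields generated per case and
  pushed through the probe/FFR pipeline;
* ``"external"`` - legacy-VTK fields read from a directory, one
  ``<case_id>.vtk`` per case; missing cases are skipped with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import fields as fp
from . import stats as st
from .errors import InvalidParameterError
from .geometry import build_centerlines
from .hemodynamics import case_grid
from .synthetic import DEFAULT_SEED, stenotic_jet_field, table3_fixture

log = logging.getLogger("bifurcfr")

#: printed reference values reproduced by validate_against_table3
EXPECTED_AB = {40.0: (0.451, 0.010), 70.0: (0.687, 0.017)}
EXPECTED_RMSE = {40.0: 0.58, 55.0: 0.47, 70.0: 0.73}
EXPECTED_ANGLE_DIFFS = {(40.0, 25.0): 0.02, (40.0, 35.0): 0.02, (40.0, 45.0): 0.02,
                        (60.0, 25.0): 0.03, (60.0, 35.0): 0.04, (60.0, 45.0): 0.05,
                        (80.0, 25.0): 0.13, (80.0, 35.0): 0.22, (80.0, 45.0): 0.33}
#: one published FFR_MB cell disagrees with its own dP_MB column by 0.0016
#: (printed 0.881 vs implied 0.879); recorded, not silently tolerated
KNOWN_FFR_MB_DISCREPANCY = ("60%-40deg-45%", 0.002)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study run."""

    source: str = "table3"               # table3 | synthetic | external
    field_dir: str | None = None         # for source='external'
    out_dir: str | None = None
    probe_offset_diameters: float = 1.0
    inlet_flow: float = 120.0
    mesh_density: int = 12
    swirl: float = 0.3
    seed: int = DEFAULT_SEED
    case_ids: tuple[str, ...] | None = None   # optional subset

    def __post_init__(self) -> None:
        if self.source not in ("table3", "synthetic", "external"):
            raise InvalidParameterError(f"unknown field source {self.source!r}")
        if self.source == "external" and not self.field_dir:
            raise InvalidParameterError("source='external' requires field_dir")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Results of a study run."""

    results: pd.DataFrame
    fits: dict
    angle_diffs: pd.DataFrame | None
    helicity_regression: tuple[float, float, float] | None
    config_digest: str
    incomplete: bool = False
    skipped: tuple[str, ...] = ()

    def results_csv(self) -> str:
        return self.results.to_csv(index=False, float_format="%.6g")


def _case_metrics_from_field(flow_field, spec, flowcond, offset_diam):
    """Probe a flow field: pressure drops, FFRs and helicity intensity."""
    cls = build_centerlines(spec)
    probe_p = fp.extract_section(flow_field, cls["PMB"], offset_diam, side="proximal")
    probe_d = fp.extract_section(flow_field, cls["DMB"], offset_diam, side="distal")
    probe_s = fp.extract_section(flow_field, cls["SB"], offset_diam, side="distal")
    p_prox = fp.mean_pressure(probe_p)
    p_dmb = fp.mean_pressure(probe_d)
    p_sb = fp.mean_pressure(probe_s)
    omega, _ = fp.vorticity(flow_field)
    return {
        "dp_mb": fp.pressure_drop(p_prox, probe_d),
        "ffr_mb": fp.ffr(p_prox, p_dmb),
        "dp_sb": fp.pressure_drop(p_prox, probe_s),
        "ffr_sb": fp.ffr(p_prox, p_sb),
        "helicity_intensity": fp.helicity_intensity(flow_field, omega),
    }


def run_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the bifurcation study end to end and assemble the report."""
    fixture = table3_fixture(inlet_flow=config.inlet_flow).set_index("case_id")
    grid = case_grid(inlet_flow=config.inlet_flow)
    if config.case_ids is not None:
        grid = [c for c in grid if c[0] in config.case_ids]

    rows, skipped = [], []
    for cid, spec, flowcond in grid:
        base = {
            "case_id": cid,
            "sb_stenosis_pct": spec.stenosis_sb_pct,
            "alpha_deg": spec.alpha_deg,
            "split_sb_pct": flowcond.split_sb * 100.0,
            "q_sb_ml_min": flowcond.q_sb,
        }
        if config.source == "table3":
            r = fixture.loc[cid]
            base.update(dp_mb=r.dp_mb, ffr_mb=r.ffr_mb, dp_sb=r.dp_sb,
                        ffr_sb=r.ffr_sb, helicity_intensity=np.nan)
        elif config.source == "synthetic":
            r = fixture.loc[cid]
            ff = stenotic_jet_field(spec, flowcond, dp_mb=float(r.dp_mb),
                                    dp_sb=float(r.dp_sb),
                                    mesh_density=config.mesh_density,
                                    swirl=config.swirl, seed=config.seed)
            base.update(_case_metrics_from_field(ff, spec, flowcond,
                                                 config.probe_offset_diameters))
        else:  # external
            path = os.path.join(config.field_dir, f"{cid}.vtk")
            if not os.path.exists(path):
                log.warning("missing external field for case %s; skipped", cid)
                skipped.append(cid)
                continue
            from .vtkio import read_flow_field

            ff = read_flow_field(path)
            base.update(_case_metrics_from_field(ff, spec, flowcond,
                                                 config.probe_offset_diameters))
        rows.append(base)

    results = pd.DataFrame(rows)
    incomplete = bool(skipped)

    fits = {}
    if not results.empty:
        severe = results[results.sb_stenosis_pct == 80.0]
        for alpha, grp in severe.groupby("alpha_deg"):
            if len(grp) >= 2:
                pts = [st.DpQPoint(q=float(r.q_sb_ml_min), dp=float(r.dp_sb),
                                   case_id=r.case_id) for r in grp.itertuples()]
                fits[float(alpha)] = st.fit_dp_q(pts)

    angle_diffs = None
    try:
        angle_diffs = st.angle_difference_table(results)
    except (InvalidParameterError, KeyError):
        incomplete = True

    regression = None
    if "helicity_intensity" in results and results["helicity_intensity"].notna().sum() >= 3:
        sub = results.dropna(subset=["helicity_intensity"])
        regression = st.linear_fit_r2(sub["helicity_intensity"], sub["dp_sb"])

    report = StudyReport(results=results, fits=fits, angle_diffs=angle_diffs,
                         helicity_regression=regression,
                         config_digest=config.digest(),
                         incomplete=incomplete, skipped=tuple(skipped))

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "results.csv"), "w") as fh:
            fh.write(report.results_csv())
        fit_json = {str(int(a)): {"A": f.a, "B": f.b, "rmse": f.rmse, "n": f.n_points}
                    for a, f in fits.items()}
        with open(os.path.join(config.out_dir, "fits.json"), "w") as fh:
            json.dump({"config": config.digest(), "fits": fit_json}, fh, indent=2)
        log.info("study results written to %s (config %s)", config.out_dir, config.digest())
    return report


# ---------------------------------------------------------------------------
# validation against the published table


@dataclass
class Check:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed_checks(self) -> list:
        return [c for c in self.checks if not c.passed]

    def summary(self) -> str:
        lines = [f"[{'PASS' if c.passed else 'FAIL'}] {c.name}: {c.detail}"
                 for c in self.checks]
        n_ok = sum(c.passed for c in self.checks)
        lines.append(f"{n_ok}/{len(self.checks)} checks passed")
        return "\n".join(lines)


def validate_against_table3(fixture: pd.DataFrame | None = None) -> ValidationReport:
    """Re-derive every published statistic from the per-case table and check
    it against the printed value.

    Covers: the through-origin quadratic dP_SB-Q_SB fits for 80 % SB stenosis
    (A, B at 40/70 deg and RMSE at all angles), the FFR-vs-angle difference
    table, the FFR <-> dP arithmetic consistency of all 27 rows, and the row
    count.  Raises on an empty fixture rather than passing silently.
    """
    df = table3_fixture() if fixture is None else fixture
    if df is None or len(df) == 0:
        raise InvalidParameterError("empty results fixture")
    checks: list[Check] = []

    checks.append(Check("row count", len(df) == 27, f"{len(df)} rows"))

    severe = df[df.sb_stenosis_pct == 80]
    for alpha, grp in severe.groupby("alpha_deg"):
        pts = [st.DpQPoint(q=float(r.q_sb_ml_min), dp=float(r.dp_sb))
               for r in grp.itertuples()]
        f = st.fit_dp_q(pts)
        a_r, b_r, rmse_r = f.rounded()
        if float(alpha) in EXPECTED_AB:
            ea, eb = EXPECTED_AB[float(alpha)]
            checks.append(Check(f"fit A,B at {alpha:.0f} deg",
                                (a_r, b_r) == (ea, eb),
                                f"A={a_r}, B={b_r} (expected {ea}, {eb})"))
        er = EXPECTED_RMSE.get(float(alpha))
        if er is not None:
            # the printed dP values carry +-0.005 rounding, which propagates
            # to ~+-0.008 in the refitted RMSE; compare within one unit of
            # the last printed digit
            checks.append(Check(f"fit RMSE at {alpha:.0f} deg", abs(f.rmse - er) <= 0.01,
                                f"RMSE={f.rmse:.4f} (printed {er})"))

    try:
        diffs = st.angle_difference_table(df)
        for (sb, split), expected in EXPECTED_ANGLE_DIFFS.items():
            got = diffs.loc[(diffs.sb_stenosis_pct == sb) &
                            (diffs.split_sb_pct == split), "ffr_sb_diff"]
            ok = len(got) == 1 and float(got.iloc[0]) == expected
            checks.append(Check(f"FFR_SB angle difference (SB {sb:.0f}%, split {split:.0f}%)",
                                ok, f"got {float(got.iloc[0]) if len(got) else 'missing'}, "
                                    f"expected {expected}"))
    except InvalidParameterError as exc:
        checks.append(Check("FFR_SB angle differences", False, str(exc)))

    tol = 0.0005 + 1e-9  # guard against binary representation of x.xx5
    sb_err = (df.ffr_sb - (100.0 - df.dp_sb) / 100.0).abs()
    checks.append(Check("FFR_SB consistent with dP_SB (all rows, <=0.0005)",
                        bool((sb_err <= tol).all()),
                        f"max |err| = {sb_err.max():.4f}"))

    mb_err = (df.ffr_mb - (100.0 - df.dp_mb) / 100.0).abs()
    known_id, known_tol = KNOWN_FFR_MB_DISCREPANCY
    others = df.case_id != known_id
    checks.append(Check("FFR_MB consistent with dP_MB (26 rows, <=0.0005)",
                        bool((mb_err[others] <= tol).all()),
                        f"max |err| = {mb_err[others].max():.4f}"))
    anom = mb_err[~others]
    checks.append(Check(f"known printed FFR_MB discrepancy in {known_id}",
                        bool(len(anom) == 1 and 0.0005 < float(anom.iloc[0]) <= known_tol),
                        f"|printed - implied| = {float(anom.iloc[0]) if len(anom) else 'n/a':.4f}"))
    return ValidationReport(checks=checks)
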