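"""One-shot reproduction run over the packaged tables.

Orchestrates the QSPR and exploration stages on the shipped descriptor
and kinetics tables: OLS and 8-component PCR calibration with
leave-one-out validation, external prediction, comparison against the
published validation table, PCA under both candidate sample sets,
Pearson sign structure, and the kinetics-table consistency audits.
Returns a plain-dict bundle suitable for JSON serialization; the CLI
writes it to disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import explore, fixtures, qspr

# Descriptor pairs whose correlation sign is a documented structural
# feature of the descriptor set (redundant RDF shells positive, the two
# anti-correlated pairs negative).
PEARSON_SIGN_CHECKS = [
    ("E3m", "GATS5m", -1),
    ("nAtomLC", "MATS4s", -1),
    ("nT10HeteroRing", "nFRing", +1),
    ("nAtomLC", "MATS5c", +1),
    ("RDF40m", "RDF45m", +1),
    ("RDF40m", "RDF85m", +1),
    ("RDF40m", "RDF115e", +1),
    ("RDF45m", "RDF85m", +1),
    ("RDF45m", "RDF115e", +1),
    ("RDF85m", "RDF115e", +1),
]


def _model_block(name: str, model, xcal, ycal, xpred, ypred) -> dict:
    rmsecv, loo_pred = qspr.loo_cv(xcal, ycal, model)
    fitted = model.fit(xcal, ycal)
    cal_pred = fitted.predict(xcal)
    ext_pred = fitted.predict(xpred)
    rep_loo = qspr.validate(ycal, loo_pred, xcal.index)
    rep_ext = qspr.validate(ypred, ext_pred, xpred.index)
    return {
        "method": name,
        "rmsec": float(np.sqrt(np.mean((cal_pred - ycal.to_numpy()) ** 2))),
        "rmsecv": rmsecv,
        "rmsep": rep_ext.rmsep,
        "loo": {
            "per_compound": rep_loo.table.to_dict(orient="records"),
            "mean_abs_error_percent": rep_loo.mean_abs_error_percent,
            "mean_error_percent": rep_loo.mean_error_percent,
            "rms_error_percent": rep_loo.rms_error_percent,
        },
        "external": {
            "per_compound": rep_ext.table.to_dict(orient="records"),
            "mean_abs_error_percent": rep_ext.mean_abs_error_percent,
            "mean_error_percent": rep_ext.mean_error_percent,
            "rms_error_percent": rep_ext.rms_error_percent,
            "r2_pred_vs_exp": rep_ext.r2_pred_vs_exp,
        },
        "intercept": fitted.intercept_,
        "coefficients": dict(zip(fitted.feature_names_in_, fitted.coef_.tolist())),
        "bw": dict(zip(fitted.feature_names_in_, fitted.bw_.tolist())),
    }


def reproduce() -> dict:
    """Run the full fixture-based analysis; returns the report bundle."""
    xcal, ycal = fixtures.calibration_response("calibration")
    xpred, ypred = fixtures.calibration_response("prediction")

    bundle: dict = {"models": {}}
    bundle["models"]["ols"] = _model_block("ols", qspr.OLSRegressor(), xcal, ycal, xpred, ypred)
    bundle["models"]["pcr8"] = _model_block("pcr8", qspr.PCRRegressor(8), xcal, ycal, xpred, ypred)

    # PCA under both candidate sample sets
    t3 = fixtures.load_fixture("table3")
    bundle["pca"] = {}
    for label, block in [("calibration20", xcal), ("all30", t3[fixtures.DESCRIPTOR_NAMES])]:
        res = explore.pca(block, center=True, scale=True)
        bundle["pca"][label] = {
            "explained_variance_percent": res.explained_variance_percent[:5].round(4).tolist(),
            "pc1": float(res.explained_variance_percent[0]),
            "pc2": float(res.explained_variance_percent[1]),
        }

    # Pearson sign structure on the calibration block
    r = explore.pearson_matrix(xcal)
    checks = []
    for a, b, sign in PEARSON_SIGN_CHECKS:
        val = float(r.loc[a, b])
        checks.append({"pair": f"{a}~{b}", "r": val, "expected_sign": sign,
                       "passed": bool(np.sign(val) == sign)})
    bundle["pearson_sign_checks"] = checks
    bundle["pearson_all_passed"] = all(c["passed"] for c in checks)

    # published-equation evaluation, both intercept variants
    bundle["printed_equation"] = {
        variant: fixtures.apply_printed_equation(
            t3[fixtures.DESCRIPTOR_NAMES], variant).round(6).to_dict()
        for variant in ("as_printed", "corrected")
    }

    # kinetics-table audits
    t01 = fixtures.t01_compat_audit()
    conv = fixtures.unit_conversion_audit()
    t4audit = fixtures.table4_error_audit()
    bundle["audits"] = {
        "t01_compat": {
            "n_checked": int((~t01["excluded"]).sum()),
            "n_excluded": int(t01["excluded"].sum()),
            "max_rel_error_checked": float(t01.loc[~t01["excluded"], "rel_error"].max()),
            "all_passed": bool(t01["passed"].all()),
        },
        "unit_conversion": {
            "max_abs_diff": float(conv["abs_diff"].max()),
            "all_passed": bool(conv["passed"].all()),
        },
        "table4_error": {
            "max_abs_diff_vs_rounded": float(t4audit["abs_diff"].max()),
            "n_within_0p15_of_rounded": int((t4audit["abs_diff"] <= 0.15).sum()),
            "all_interval_consistent": bool(t4audit["passed"].all()),
        },
    }
    bundle["all_audits_passed"] = all(
        bundle["audits"][k]["all_passed" if "all_passed" in bundle["audits"][k]
                            else "all_interval_consistent"]
        for k in bundle["audits"]
    ) and bundle["pearson_all_passed"]
    return bundle
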