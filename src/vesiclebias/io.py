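"""Vesicle-table I/O, run configuration, and the analysis pipeline.

The on-disk vesicle table is delimited text (comma by default, tab
accepted) with a header row and columns::

    vesicle_id, experiment_id, receptor_variant, ligand, ligand_conc_nM,
    py_site, receptor_fluor, antibody_fluor, ligand_fluor

``ligand_fluor`` may be empty. ``run_pipeline`` orchestrates the full
analysis: Hill fits per condition, bias plots and relative coefficients,
transducer fits and absolute coefficients for three-channel data, all
written as JSON + delimited tables with provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vesiclebias import bias as bias_mod
from vesiclebias import dose_response as dr
from vesiclebias import transducer as tr
from vesiclebias.stats import MCSettings
from vesiclebias.synthetic import (
    VESICLE_COLUMNS,
    GenerativeConfig,
    simulate_dose_response,
    simulate_three_channel,
)

logger = logging.getLogger("vesiclebias")

__all__ = ["read_vesicle_table", "write_vesicle_table", "RunConfig", "run_pipeline"]

REQUIRED_COLUMNS = VESICLE_COLUMNS[:-1]  # ligand_fluor is optional


class TableFormatError(ValueError):
    pass


def _parse_float(series: pd.Series) -> pd.Series:
    """Exact (round-trippable) float parsing; unparseable/empty -> NaN.

    ``pd.to_numeric`` uses a fast parser that can be off by one ulp.
    """

    def conv(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv).astype(float)


def read_vesicle_table(path, *, strict: bool = False, sep: str | None = None):
    """Read a vesicle table; returns ``(records, report)``.

    ``report`` lists malformed rows as ``(line_number, message)`` using
    1-based file line numbers (header is line 1). In strict mode any
    malformed row raises :class:`TableFormatError`. Malformed rows are
    dropped from the returned records.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {missing}")
    if "ligand_fluor" not in table.columns:
        table["ligand_fluor"] = ""

    report: list[tuple[int, str]] = []
    numeric = {"ligand_conc_nM", "receptor_fluor", "antibody_fluor"}
    parsed = {}
    bad = np.zeros(len(table), dtype=bool)
    for col in sorted(numeric):
        vals = _parse_float(table[col])
        for i in np.flatnonzero(vals.isna().to_numpy()):
            report.append((i + 2, f"column {col}: unparseable value {table[col].iloc[i]!r}"))
        bad |= vals.isna().to_numpy()
        parsed[col] = vals
    ligfluor = _parse_float(table["ligand_fluor"])
    unparseable_lig = table["ligand_fluor"].ne("") & ligfluor.isna()
    for i in np.flatnonzero(unparseable_lig.to_numpy()):
        report.append((i + 2, f"column ligand_fluor: unparseable value {table['ligand_fluor'].iloc[i]!r}"))
    bad |= unparseable_lig.to_numpy()
    parsed["ligand_fluor"] = ligfluor

    with np.errstate(invalid="ignore"):
        nonpos = parsed["receptor_fluor"].to_numpy() <= 0
    for i in np.flatnonzero(nonpos & ~bad):
        report.append((i + 2, "receptor_fluor must be > 0"))
    bad |= np.nan_to_num(nonpos, nan=False)
    with np.errstate(invalid="ignore"):
        neg_conc = parsed["ligand_conc_nM"].to_numpy() < 0
    for i in np.flatnonzero(neg_conc & ~bad):
        report.append((i + 2, "ligand_conc_nM must be >= 0"))
    bad |= np.nan_to_num(neg_conc, nan=False)

    if strict and report:
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in sorted(report))
        raise TableFormatError(f"malformed rows: {lines}")

    out = table.copy()
    for col, vals in parsed.items():
        out[col] = vals
    out = out.loc[~bad].reset_index(drop=True)
    return out, sorted(report)


def write_vesicle_table(records: pd.DataFrame, path, *, sep: str = ",") -> None:
    """Write a vesicle table; full float precision (round-trips exactly)."""
    out = records.loc[:, [c for c in VESICLE_COLUMNS if c in records.columns]]
    out.to_csv(path, sep=sep, index=False)  # default repr round-trips doubles


_RUNCONFIG_KEYS = {
    "inputs", "simulate", "e0_mode", "fit_target", "response_a", "response_b",
    "reference_ligand", "reference_variant", "mc", "bin", "out_dir", "seed",
    "strict",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration. Unknown keys are rejected."""

    inputs: tuple = ()
    simulate: tuple = ()  # each: {"labels": {...}, "config": {...}, "three_channel": bool}
    e0_mode: str | float = "subtract"
    fit_target: str = "vesicles"
    response_a: str = "Y1068"
    response_b: str = "Y1173"
    reference_ligand: str = "EGF"
    reference_variant: str = "WT"
    mc: MCSettings = field(default_factory=MCSettings)
    bin_width: float = 0.1
    bin_min_n: int = 50
    out_dir: str = "results"
    seed: int = 0
    strict: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if raw.get("fit_target", "vesicles") not in {"vesicles", "means"}:
            raise ValueError("fit_target must be 'vesicles' or 'means'")
        mc_raw = raw.get("mc", {})
        mc = MCSettings(
            n_draws=int(mc_raw.get("n_draws", 1_000_000)),
            seed=int(mc_raw.get("seed", raw.get("seed", 0))),
        )
        bin_raw = raw.get("bin", {})
        return cls(
            inputs=tuple(raw.get("inputs", ())),
            simulate=tuple(raw.get("simulate", ())),
            e0_mode=raw.get("e0_mode", "subtract"),
            fit_target=raw.get("fit_target", "vesicles"),
            response_a=raw.get("response_a", "Y1068"),
            response_b=raw.get("response_b", "Y1173"),
            reference_ligand=raw.get("reference_ligand", "EGF"),
            reference_variant=raw.get("reference_variant", "WT"),
            mc=mc,
            bin_width=float(bin_raw.get("width", 0.1)),
            bin_min_n=int(bin_raw.get("min_n", 50)),
            out_dir=str(raw.get("out_dir", "results")),
            seed=int(raw.get("seed", 0)),
            strict=bool(raw.get("strict", False)),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        return cls.from_dict(raw or {})


def _load_records(config: RunConfig) -> pd.DataFrame:
    frames = []
    for p in config.inputs:
        records, report = read_vesicle_table(p, strict=config.strict)
        for line, msg in report:
            logger.warning("%s line %d: %s", p, line, msg)
        frames.append(records)
    for i, sim in enumerate(config.simulate):
        cfg_fields = dict(sim.get("config", {}))
        cfg_fields.setdefault("seed", config.seed + i)
        gen = GenerativeConfig(**cfg_fields)
        labels = dict(sim.get("labels", {}))
        if sim.get("three_channel", False):
            frames.append(simulate_three_channel(gen, labels))
        else:
            frames.append(simulate_dose_response(gen, labels))
    if not frames:
        raise ValueError("config provides neither inputs nor simulate blocks")
    return pd.concat(frames, ignore_index=True)


def _fit_condition(records: pd.DataFrame, config: RunConfig) -> dr.HillFit:
    if config.fit_target == "means":
        e0_mode = config.e0_mode
        if e0_mode == "subtract":
            e0_mode, _ = dr.estimate_constitutive(records)
        points = dr.aggregate(records)
        conc = np.array([p.ligand_conc for p in points])
        resp = np.array([p.mean_ratio for p in points])
        return dr.fit_hill(conc=conc, response=resp, e0_mode=e0_mode)
    return dr.fit_hill(records, e0_mode=config.e0_mode)


def run_pipeline(config: RunConfig | dict, out_dir=None) -> dict:
    """Run the full analysis and write the result bundle.

    For each (variant, ligand, site): a Hill fit. For each ligand vs the
    reference ligand (per variant) and each variant vs the reference
    variant (per ligand): bias plot + relative coefficient with MC SE.
    For conditions carrying a ligand channel: transducer fit, efficiency,
    and the absolute-coefficient chain. Deterministic given config + seed.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = _load_records(config)
    site_a, site_b = config.response_a, config.response_b

    results: dict = {"hill_fits": {}, "bias_plots": {}, "bias_coefficients": [], "transducer_fits": {}}

    conditions = sorted(
        records.groupby(["receptor_variant", "ligand", "py_site"]).groups.keys()
    )
    fits: dict[tuple, dr.HillFit] = {}
    points: dict[tuple, list] = {}
    for variant, ligand, site in conditions:
        sub = records[
            (records["receptor_variant"] == variant)
            & (records["ligand"] == ligand)
            & (records["py_site"] == site)
        ]
        try:
            fit = _fit_condition(sub, config)
        except ValueError as exc:
            raise ValueError(f"condition ({variant}, {ligand}, {site}): {exc}") from exc
        fits[(variant, ligand, site)] = fit
        points[(variant, ligand, site)] = dr.aggregate(sub)
        results["hill_fits"]["/".join((variant, ligand, site))] = fit.to_dict()

    variants = sorted({v for v, _, _ in conditions})
    ligands = sorted({l for _, l, _ in conditions})

    def has_pair(variant, ligand):
        return (variant, ligand, site_a) in fits and (variant, ligand, site_b) in fits

    # bias plots + ligand-induced coefficients vs the reference ligand
    for variant in variants:
        for ligand in ligands:
            if not has_pair(variant, ligand):
                continue
            series = bias_mod.bias_plot(
                points[(variant, ligand, site_a)], points[(variant, ligand, site_b)]
            )
            results["bias_plots"][f"{variant}/{ligand}"] = dataclasses.asdict(series)
            ref = config.reference_ligand
            if ligand != ref and has_pair(variant, ref):
                coeff = bias_mod.beta_lig(
                    fits[(variant, ligand, site_a)], fits[(variant, ligand, site_b)],
                    fits[(variant, ref, site_a)], fits[(variant, ref, site_b)],
                    ligand=ligand, reference=ref,
                    response_a=site_a, response_b=site_b, mc=config.mc,
                )
                results["bias_coefficients"].append(coeff.to_dict())

    # mutation-induced coefficients vs the reference variant
    ref_var = config.reference_variant
    for variant in variants:
        if variant == ref_var:
            continue
        for ligand in ligands:
            if has_pair(variant, ligand) and has_pair(ref_var, ligand):
                coeff = bias_mod.beta_mut(
                    (fits[(variant, ligand, site_a)], fits[(variant, ligand, site_b)]),
                    (fits[(ref_var, ligand, site_a)], fits[(ref_var, ligand, site_b)]),
                    mutant=variant, wildtype=ref_var,
                    response_a=site_a, response_b=site_b, mc=config.mc,
                )
                results["bias_coefficients"].append(coeff.to_dict())

    # transducer route for three-channel conditions
    tfits: dict[tuple, tr.TransducerFit] = {}
    for variant, ligand, site in conditions:
        sub = records[
            (records["receptor_variant"] == variant)
            & (records["ligand"] == ligand)
            & (records["py_site"] == site)
        ]
        if sub["ligand_fluor"].isna().all():
            continue
        f_bound = tr.scale_bound_fraction(sub)
        e0, _ = dr.estimate_constitutive(sub)
        resp = np.asarray(dr.compute_ratios(sub), dtype=float) - e0
        tfit = tr.fit_transducer(f_bound, resp, mc=config.mc)
        tfits[(variant, ligand, site)] = tfit
        key = "/".join((variant, ligand, site))
        results["transducer_fits"][key] = tfit.to_dict()
        binned = tr.bin_transducer(f_bound, resp, config.bin_width, config.bin_min_n)
        results["transducer_fits"][key]["binned"] = dataclasses.asdict(binned)

    # absolute coefficients where both sites have transducer fits
    for variant in variants:
        for ligand in ligands:
            ka = tfits.get((variant, ligand, site_a))
            kb = tfits.get((variant, ligand, site_b))
            if ka is None or kb is None or not (ka.converged and kb.converged):
                continue
            star = bias_mod.beta_star_from_kresp(
                ka.k_resp, kb.k_resp, se_a=ka.k_resp_se, se_b=kb.k_resp_se,
                entity=f"{variant}/{ligand}", response_a=site_a, response_b=site_b,
                mc=config.mc,
            )
            results["bias_coefficients"].append(star.to_dict())
            # chain to ligands with only relative coefficients
            for rec in results["bias_coefficients"]:
                if (
                    rec["kind"] == "ligand"
                    and rec["reference_entity"] == ligand
                ):
                    rel = bias_mod.BiasCoefficient(
                        value=rec["value"], se=rec["se"], kind=rec["kind"],
                        response_a=rec["response_A"], response_b=rec["response_B"],
                        test_entity=rec["test_entity"], reference_entity=rec["reference_entity"],
                    )
                    chained = bias_mod.beta_star_transfer(
                        rel,
                        bias_mod.BiasCoefficient(
                            value=star.value, se=star.se, kind="absolute",
                            response_a=star.response_a, response_b=star.response_b,
                            test_entity=ligand, reference_entity="absolute-scale",
                        ),
                        mc=config.mc,
                    )
                    results["bias_coefficients"].append(chained.to_dict())

    provenance = {
        "config_hash": hashlib.sha256(
            json.dumps(_config_as_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "software": "vesiclebias",
        "version": _version(),
        "n_records": int(len(records)),
        "e0_mode": config.e0_mode,
        "fit_target": config.fit_target,
        "beta_star_sign_convention": "beta_star_test = beta_rel + beta_star_ref",
    }
    results["provenance"] = provenance

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    _write_tables(results, out)
    return results


def _version() -> str:
    from vesiclebias import __version__

    return __version__


def _config_as_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["mc"] = {"n_draws": config.mc.n_draws, "seed": config.mc.seed}
    return d


def _write_tables(results: dict, out: Path) -> None:
    rows = []
    for key, series in results["bias_plots"].items():
        for i, conc in enumerate(series["ligand_conc"]):
            rows.append(
                {
                    "condition": key,
                    "ligand_conc_nM": conc,
                    "mean_A": series["mean_a"][i],
                    "sem_A": series["sem_a"][i],
                    "mean_B": series["mean_b"][i],
                    "sem_B": series["sem_b"][i],
                    "n_A": series["n_a"][i],
                    "n_B": series["n_b"][i],
                }
            )
    if rows:
        pd.DataFrame(rows).to_csv(out / "bias_plots.csv", index=False, float_format="%.17g")
    if results["bias_coefficients"]:
        flat = [
            {k: v for k, v in rec.items() if k != "meta"}
            for rec in results["bias_coefficients"]
        ]
        pd.DataFrame(flat).to_csv(out / "bias_coefficients.csv", index=False, float_format="%.17g")
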