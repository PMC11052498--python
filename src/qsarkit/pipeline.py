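"""End-to-end orchestration: config handling, runs, table-shaped reports.

A run is described by a YAML config (strict schema: unknown keys are
rejected) and produces delimited-text reports whose headers embed the
package version and a hash of the fully-resolved config, so identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import io
import sys
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import load_compound_table, ordinal_split
from .hologram import HologramParams, hologram_matrix
from .pls import fit_pls, select_components
from .rgroup import Fragment, RGroupCutSpec, TopomerFieldModel, cut_rgroups, screen_library
from .synthetic import default_series_spec, generate_rgroup_series
from .validation import PredictionTable, validate_predictions

__all__ = ["RunConfig", "run_model", "run_validation", "run_screen", "config_hash"]

_SCHEMA = {
    "data": {"path", "ic50_unit", "split_period", "split_start"},
    "hologram": {"size_min", "size_max", "flags", "length"},
    "fields": {"mode", "spacing", "margin", "cutoff", "attenuation", "min_sigma"},
    "pls": {"n_components", "max_components", "scale"},
    "validation": {"predictions", "pred_column", "r2_model"},
    "screen": {"scaffold", "library", "position", "max_distance",
               "min_contribution", "n_components"},
    "synthetic": {"n", "noise_sd"},
}
_TOP_SCALARS = {"seed", "outdir"}


@dataclass
class RunConfig:
    """Validated run configuration; see ``RunConfig.from_yaml``."""

    raw: dict
    seed: int = 0
    outdir: Path = Path(".")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_SCHEMA) - _TOP_SCALARS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for section, allowed in _SCHEMA.items():
            sub = d.get(section) or {}
            if not isinstance(sub, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown key(s) in {section!r}: {sorted(bad)}")
        return cls(raw=d, seed=int(d.get("seed", 0)),
                   outdir=Path(d.get("outdir", ".")))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})


def config_hash(config: RunConfig) -> str:
    canon = yaml.safe_dump(config.raw, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (f"# qsarkit {__version__}\n"
            f"# config_hash {config_hash(config)}\n")


def _write_report(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(_header(config))
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    path.write_text(buf.getvalue())


def _load_series(config: RunConfig):
    """Compound set + per-compound fragment choices (synthetic runs only)."""
    data = config.section("data")
    if data.get("path"):
        cset = load_compound_table(data["path"], ic50_unit=data.get("ic50_unit", "M"))
        choices = None
    else:
        syn = config.section("synthetic")
        spec = default_series_spec(n=int(syn.get("n", 60)),
                                   noise_sd=float(syn.get("noise_sd", 0.1)),
                                   seed=config.seed)
        cset, choices = generate_rgroup_series(spec)
    period = int(data.get("split_period", 4))
    start = int(data.get("split_start", 2))
    return ordinal_split(cset, period, start), choices


def run_model(config: RunConfig) -> pd.DataFrame:
    """Descriptors -> component selection -> fit -> internal stats report.

    Uses hologram descriptors on the training subset; reports N, q^2,
    r^2, SEE, SEEcv and F in a one-row table, written to
    ``<outdir>/model_stats.tsv``.
    """
    cset, _ = _load_series(config)
    train = cset.train
    holo = config.section("hologram")
    params = HologramParams(
        size_min=int(holo.get("size_min", 2)), size_max=int(holo.get("size_max", 4)),
        flags=tuple(holo.get("flags", ["A", "Ch"])), length=int(holo.get("length", 257)),
    )
    X = hologram_matrix(train, params)
    y = np.asarray(train.activities())
    pls = config.section("pls")
    if pls.get("n_components"):
        n_comp = int(pls["n_components"])
    else:
        n_comp, _ = select_components(X, y, int(pls.get("max_components", 6)),
                                      scale=bool(pls.get("scale", False)))
    state = fit_pls(X, y, n_comp, scale=bool(pls.get("scale", False)))
    report = pd.DataFrame([{
        "n_train": len(train), "N": state.n_components, "HL": params.length,
        "flags": "/".join(params.flags),
        "size": f"{params.size_min}-{params.size_max}",
        "q2": round(state.q2, 3), "r2": round(state.r2, 3),
        "SEE": round(state.see, 3), "SEEcv": round(state.see_cv, 3),
        "F": round(state.f_statistic, 3),
    }])
    _write_report(report, config.outdir / "model_stats.tsv", config)
    return report


def run_validation(config: RunConfig) -> tuple[pd.DataFrame, bool]:
    """External-validation battery over a prediction table.

    The predictions file needs columns ordinal, pic50_exp (or y),
    predicted values (``pred_column``) and role.  Writes the criteria
    report to ``<outdir>/validation_report.tsv`` and returns it together
    with the overall pass verdict.
    """
    val = config.section("validation")
    if not val.get("predictions"):
        raise ValueError("validation.predictions path is required")
    df = pd.read_csv(val["predictions"])
    if "role" not in df.columns:
        raise ValueError("predictions table must carry a 'role' column")
    table = PredictionTable.from_frame(df, pred_column=val.get("pred_column", "y_pred"))
    report = validate_predictions(table, r_sq_model=val.get("r2_model"))
    frame = report.to_frame()
    _write_report(frame, config.outdir / "validation_report.tsv", config)
    for w in report.warnings:
        print(f"warning: {w}", file=sys.stderr)
    return frame, report.passed()


def run_screen(config: RunConfig) -> pd.DataFrame:
    """Fit a fragment-field model on a cut series and rank a library.

    The training structures are cut at the configured scaffold, a PLS
    model over per-position fragment fields is fitted, and the library
    fragments are ranked by contribution at the query position (distance
    to the currently best training fragment capped by ``max_distance``).
    Writes ``<outdir>/screen_candidates.tsv``.
    """
    scr = config.section("screen")
    if not scr.get("scaffold"):
        raise ValueError("screen.scaffold is required")
    cset, choices = _load_series(config)
    cut = RGroupCutSpec(scr["scaffold"])
    if choices is None:
        choices = [cut_rgroups(r.smiles, cut).fragments for r in cset]
    model = TopomerFieldModel(cut.labels(),
                              n_components=int(scr.get("n_components", 4)))
    model.fit(choices, np.asarray(cset.activities()))

    position = scr.get("position", cut.labels()[-1])
    if scr.get("library"):
        with open(scr["library"]) as fh:
            library = [Fragment(line.split()[0]) for line in fh
                       if line.strip() and not line.startswith("#")]
    else:
        library = list({ch[position].canonical(): ch[position] for ch in choices}.values())
    best = max(((ch[position], model.contribution(position, ch[position]))
                for ch in choices), key=lambda t: t[1])[0]
    rows = screen_library(
        library, best, model, position,
        max_distance=float(scr.get("max_distance", np.inf)),
        min_contribution=float(scr.get("min_contribution", -np.inf)))
    frame = pd.DataFrame(
        [{"smiles": r["smiles"], "distance": round(r["distance"], 6),
          "contribution": round(r["contribution"], 6)} for r in rows],
        columns=["smiles", "distance", "contribution"])
    _write_report(frame, config.outdir / "screen_candidates.tsv", config)
    return frame
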