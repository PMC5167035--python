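"""CSV/JSON/YAML formats and run manifests.

Panel data travel as three CSVs (counts; site covariates; time-varying
covariates).  Chains are written as a long ("tidy") draws CSV plus a model
-indicator CSV so that partitions with varying block counts serialize
uniformly; partition labels use the canonical brace form "{bt, gt}, {ct}".
Manifests capture seed, config hash and package version and are written
last (atomically), so any artifact can be regenerated from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import PanelData, Partition, SharingStructure, ModelState
from .rjmcmc import ChainOutput

__all__ = [
    "read_panel",
    "write_panel",
    "write_chain",
    "read_chain",
    "write_truth",
    "load_config",
    "write_manifest",
]


def read_panel(
    counts_csv,
    site_cov_csv,
    timevar_cov_csv,
    standardize: bool = True,
) -> PanelData:
    """Load and validate a panel from three CSV files.

    ``counts_csv``: columns species, site, year, value.  ``site_cov_csv``:
    site plus one named column per site covariate.  ``timevar_cov_csv``:
    site, year plus one named column per time-varying covariate.  Windows
    are inferred per site from the years present; interior gaps are
    rejected (missing-year augmentation is out of scope), as are negative
    counts, missing covariate rows and (when standardizing) constant
    covariate columns.
    """
    counts = pd.read_csv(counts_csv, float_precision="round_trip")
    site_cov = pd.read_csv(site_cov_csv, float_precision="round_trip")
    tv_cov = pd.read_csv(timevar_cov_csv, float_precision="round_trip")
    for col in ("species", "site", "year", "value"):
        if col not in counts.columns:
            raise ValueError(f"counts file lacks column {col!r}")
    if (counts["value"] < 0).any():
        raise ValueError("negative count values")
    species = sorted(counts["species"].astype(str).unique())
    sites = sorted(counts["site"].astype(str).unique())
    counts = counts.assign(
        species=counts["species"].astype(str),
        site=counts["site"].astype(str),
        year=counts["year"].astype(int),
    )
    sp_idx = {s: k for k, s in enumerate(species)}
    window_start, window_len = [], []
    y_cols = []
    v_names = [c for c in tv_cov.columns if c not in ("site", "year")]
    x_names = [c for c in site_cov.columns if c != "site"]
    if not x_names or not v_names:
        raise ValueError("covariate files must contain at least one covariate column")
    site_cov = site_cov.assign(site=site_cov["site"].astype(str)).set_index("site")
    tv_cov = tv_cov.assign(
        site=tv_cov["site"].astype(str), year=tv_cov["year"].astype(int)
    ).set_index(["site", "year"])
    missing_x = [s for s in sites if s not in site_cov.index]
    if missing_x:
        raise ValueError(f"missing site covariates for: {missing_x}")
    x = site_cov.loc[sites, x_names].to_numpy(dtype=float)
    v_rows = []
    for site in sites:
        sub = counts[counts["site"] == site]
        years = np.sort(sub["year"].unique())
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError(
                f"site {site}: interior missing year(s) in {years.tolist()}"
            )
        window_start.append(int(years[0]))
        window_len.append(len(years))
        block = np.full((len(species), len(years)), np.nan)
        for _, row in sub.iterrows():
            block[sp_idx[row["species"]], row["year"] - years[0]] = row["value"]
        if np.isnan(block).any():
            miss = np.argwhere(np.isnan(block))
            raise ValueError(
                f"site {site}: missing observations for "
                f"{[(species[a], int(years[0] + b)) for a, b in miss[:5]]}"
            )
        y_cols.append(block)
        offenders = [
            (site, int(t)) for t in years if (site, int(t)) not in tv_cov.index
        ]
        if offenders:
            raise ValueError(f"missing time-varying covariates for: {offenders[:5]}")
        v_rows.append(
            tv_cov.loc[[(site, int(t)) for t in years], v_names].to_numpy(dtype=float)
        )
    y = np.concatenate(y_cols, axis=1)
    v = np.concatenate(v_rows, axis=0)
    meta = None
    if standardize:
        meta = {"x": {}, "v": {}}
        for j, name in enumerate(x_names):
            m, sd = float(x[:, j].mean()), float(x[:, j].std(ddof=0))
            if sd == 0:
                raise ValueError(f"site covariate {name!r} is constant (zero sd)")
            x[:, j] = (x[:, j] - m) / sd
            meta["x"][name] = {"mean": m, "sd": sd}
        for j, name in enumerate(v_names):
            m, sd = float(v[:, j].mean()), float(v[:, j].std(ddof=0))
            if sd == 0:
                raise ValueError(f"time covariate {name!r} is constant (zero sd)")
            v[:, j] = (v[:, j] - m) / sd
            meta["v"][name] = {"mean": m, "sd": sd}
    return PanelData(
        species=species,
        sites=sites,
        window_start=np.array(window_start),
        window_len=np.array(window_len),
        y=y,
        v=v,
        x=x,
        x_names=x_names,
        v_names=v_names,
        standardization=meta,
    )


def write_panel(data: PanelData, outdir) -> dict[str, Path]:
    """Write the three panel CSVs (full-precision, locale-independent)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    off = data.offsets
    rows = []
    for i, site in enumerate(data.sites):
        for k, year in enumerate(data.site_years(i)):
            for s, sp in enumerate(data.species):
                rows.append((sp, site, int(year), repr(float(data.y[s, off[i] + k]))))
    counts = outdir / "counts.csv"
    pd.DataFrame(rows, columns=["species", "site", "year", "value"]).to_csv(
        counts, index=False
    )
    sc = pd.DataFrame(data.x, columns=data.x_names)
    sc.insert(0, "site", data.sites)
    site_path = outdir / "site_covariates.csv"
    sc.to_csv(site_path, index=False, float_format="%.17g")
    tv_rows = []
    for i, site in enumerate(data.sites):
        for k, year in enumerate(data.site_years(i)):
            tv_rows.append(
                [site, int(year)] + [float(z) for z in data.v[off[i] + k]]
            )
    tv = pd.DataFrame(tv_rows, columns=["site", "year"] + data.v_names)
    tv_path = outdir / "time_covariates.csv"
    tv.to_csv(tv_path, index=False, float_format="%.17g")
    return {"counts": counts, "site_covariates": site_path, "time_covariates": tv_path}


_PART_RE = re.compile(r"\{([^}]*)\}")


def partition_from_label(label: str, species: list[str]) -> Partition:
    idx = {s: k for k, s in enumerate(species)}
    blocks = []
    for grp in _PART_RE.findall(label):
        blocks.append([idx[s.strip()] for s in grp.split(",")])
    return Partition(blocks)


def write_chain(chain: ChainOutput, outdir) -> dict[str, Path]:
    """Serialize a chain: long draws CSV (iteration, parameter, value) for
    all non-latent scalars, and a model-indicator CSV (iteration, family,
    partition label, plus one nu-inclusion row per included pair)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = chain.species
    recs = []
    D = chain.n_draws
    for d in range(D):
        for s, name in enumerate(sp):
            recs.append((d, f"alpha[{name}]", chain.draws["alpha"][d, s]))
        for fam in chain.families:
            for s, name in enumerate(sp):
                recs.append((d, f"{fam}[{name}]", chain.draws[fam][d, s]))
        inc = chain.draws["nu_included"][d]
        for l, s in np.argwhere(inc):
            recs.append(
                (d, f"nu[{sp[l]}->{sp[s]}]", chain.draws["nu"][d, l, s])
            )
        recs.append((d, "sigma2_eps", chain.draws["sigma2_eps"][d]))
        for s, name in enumerate(sp):
            recs.append((d, f"sigma2[{name}]", chain.draws["sigma2_s"][d, s]))
    draws_path = outdir / "draws.csv"
    pd.DataFrame(recs, columns=["iteration", "parameter", "value"]).to_csv(
        draws_path, index=False, float_format="%.17g"
    )
    mrecs = []
    for fam in chain.families:
        for d, part in enumerate(chain.partitions[fam]):
            mrecs.append((d, fam, part.label(sp)))
    models_path = outdir / "models.csv"
    pd.DataFrame(mrecs, columns=["iteration", "family", "partition"]).to_csv(
        models_path, index=False
    )
    return {"draws": draws_path, "models": models_path}


_NAME_RE = re.compile(r"^(?P<base>[^\[\]]+)(\[(?P<arg>[^\]]+)\])?$")


def read_chain(outdir, species: list[str] | None = None) -> ChainOutput:
    """Rebuild a ChainOutput from draws.csv / models.csv (latent effects
    are not serialized and are absent from the result)."""
    outdir = Path(outdir)
    draws = pd.read_csv(outdir / "draws.csv")
    models = pd.read_csv(outdir / "models.csv")
    if draws.empty:
        raise ValueError("empty chain file")
    families = sorted(models["family"].unique())
    if species is None:
        alpha_names = draws[draws["parameter"].str.startswith("alpha[")]
        species = sorted(
            {m.group("arg") for m in map(_NAME_RE.match, alpha_names["parameter"])}
        )
    n_s = len(species)
    sp_idx = {s: k for k, s in enumerate(species)}
    D = int(draws["iteration"].max()) + 1
    rec = {
        "alpha": np.full((D, n_s), np.nan),
        "nu": np.zeros((D, n_s, n_s)),
        "nu_included": np.zeros((D, n_s, n_s), dtype=bool),
        "sigma2_eps": np.full(D, np.nan),
        "sigma2_s": np.full((D, n_s), np.nan),
    }
    for fam in families:
        rec[fam] = np.full((D, n_s), np.nan)
    for it, name, val in draws.itertuples(index=False):
        m = _NAME_RE.match(name)
        base, arg = m.group("base"), m.group("arg")
        if base == "alpha":
            rec["alpha"][it, sp_idx[arg]] = val
        elif base == "nu":
            l_name, s_name = arg.split("->")
            l, s = sp_idx[l_name], sp_idx[s_name]
            rec["nu"][it, l, s] = val
            rec["nu_included"][it, l, s] = True
        elif base == "sigma2_eps":
            rec["sigma2_eps"][it] = val
        elif base == "sigma2":
            rec["sigma2_s"][it, sp_idx[arg]] = val
        elif base in rec:
            rec[base][it, sp_idx[arg]] = val
    parts = {
        fam: [None] * D for fam in families
    }
    for it, fam, label in models.itertuples(index=False):
        parts[fam][it] = partition_from_label(label, species)
    return ChainOutput(
        species=species, families=families, draws=rec, partitions=parts, meta={}
    )


def write_truth(truth: tuple[ModelState, SharingStructure], path) -> None:
    state, sharing = truth
    doc = {
        "alpha": state.alpha.tolist(),
        "values": {k: v.tolist() for k, v in state.values.items()},
        "partitions": {
            k: [list(b) for b in p.blocks] for k, p in sharing.partitions.items()
        },
        "nu": [[int(l), int(s), float(v)] for (l, s), v in sorted(state.nu.items())],
        "sigma2_eps": float(state.sigma2_eps),
        "sigma2_s": state.sigma2_s.tolist(),
        "eps": state.eps.tolist(),
        "delta": state.delta.tolist(),
        "mu0": state.mu0.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, *, command: str, seed, config: dict, outputs: dict) -> None:
    """Write the run manifest atomically (temp file + rename) so a crash
    never leaves a partial manifest behind."""
    from . import __version__

    doc = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "covsync_version": __version__,
        "numpy_version": np.__version__,
    }
    path = Path(path)
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(doc, indent=1))
    os.replace(tmp, path)
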