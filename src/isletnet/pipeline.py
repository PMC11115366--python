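"""End-to-end pipeline orchestration from a single config.

A :class:`PipelineConfig` names the input recording (or a ``simulate``
block), the bands to analyze, the similarity methods and construction
methods to apply, and the metrics options.  :func:`run_pipeline` executes
every requested (band x similarity x construction) combination, writes
similarity matrices, edge lists and metric records into the output
directory, compares all constructed networks pairwise, and finishes with a
manifest recording the package version, the seed, the config hash and a
hash of every output file, so a rerun with the same config and seed can be
verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import compare_networks, nsi
from .construct import (
    fixed_kavg_network,
    fixed_threshold_network,
    geometric_network,
    multilayer_mst_network,
)
from .exceptions import ParameterError
from .io import (
    read_coords_csv,
    read_recording_csv,
    read_recording_hdf5,
    write_edge_list,
    write_similarity_csv,
)
from .metrics import compute_metrics
from .preprocess import FilterSpec, bandpass_filter, binarize, relative_active_time, smooth
from .recording import CalciumRecording
from .similarity import coactivity_matrix, nmi_matrix, pearson_matrix
from .simulate import IsletSimConfig, generate_islet

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_SIMILARITY_METHODS = ("correlation", "coactivity", "mutual_information")
_CONSTRUCTION_METHODS = ("fixed_threshold", "fixed_kavg", "multilayer_mst")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.  See the module docstring."""

    output_dir: str = "isletnet_out"
    seed: int = 0
    input: dict | None = None      # {traces, coords?, fs?, format?}
    simulate: dict | None = None   # IsletSimConfig overrides
    interval: list[float] | None = None  # [start_s, end_s]
    bands: list[str] = field(default_factory=lambda: ["fast"])
    smooth_window: int = 1
    binarize_params: dict = field(default_factory=dict)
    similarity: list[str] = field(default_factory=lambda: ["correlation"])
    construction: list[dict] = field(default_factory=lambda: [{"method": "fixed_kavg", "target_kavg": 8.0}])
    geometric: dict | None = None  # {mode, value} -> adds a structural reference network
    metrics: dict = field(default_factory=dict)  # sw_randomizations, hub_fraction, n_bins
    compare: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ParameterError("config must have exactly one of 'input' or 'simulate'")
        for m in self.similarity:
            if m not in _SIMILARITY_METHODS:
                raise ParameterError(f"unknown similarity method {m!r}")
        for c in self.construction:
            if c.get("method") not in _CONSTRUCTION_METHODS:
                raise ParameterError(f"unknown construction method {c.get('method')!r}")
        for b in self.bands:
            if b != "raw" and b not in ("fast", "slow", "oscillatory"):
                raise ParameterError(f"unknown band {b!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def canonical_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go and
        how verbosely we log do not change the science)."""
        payload = {k: v for k, v in self.__dict__.items() if k not in ("output_dir", "log_level")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_recording(cfg: PipelineConfig) -> CalciumRecording:
    if cfg.simulate is not None:
        sim_cfg = IsletSimConfig(**{"seed": cfg.seed, **cfg.simulate})
        return generate_islet(sim_cfg).recording
    spec = dict(cfg.input)
    traces_path = Path(spec["traces"])
    fmt = spec.get("format") or ("hdf5" if traces_path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        rec = read_recording_hdf5(traces_path)
    else:
        rec = read_recording_csv(traces_path, fs=spec.get("fs"))
    if spec.get("coords"):
        rec.coords = read_coords_csv(spec["coords"], cell_ids=rec.cell_ids)
    return rec


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    rec = _load_recording(cfg)
    if cfg.interval is not None:
        rec = rec.slice_time(cfg.interval[0], cfg.interval[1])

    met_opts = {
        "sw_randomizations": int(cfg.metrics.get("sw_randomizations", 20)),
        "seed": cfg.seed,
    }
    hub_fraction = float(cfg.metrics.get("hub_fraction", 1 / 6))

    networks: dict[str, object] = {}
    written: list[Path] = []

    for band in cfg.bands:
        if band == "raw":
            band_rec = rec
        else:
            band_rec = bandpass_filter(rec, FilterSpec.named(band))
        if cfg.smooth_window > 1:
            band_rec = band_rec.with_traces(smooth(band_rec.traces, cfg.smooth_window))

        bin_act = None
        matrices = {}
        for method in cfg.similarity:
            if method == "correlation":
                S = pearson_matrix(band_rec, source={"band": band})
            else:
                if bin_act is None:
                    bin_act = binarize(band_rec, **cfg.binarize_params)
                S = (coactivity_matrix if method == "coactivity" else nmi_matrix)(
                    bin_act, source={"band": band}
                )
            matrices[method] = S
            p = out / f"similarity_{band}_{method}.csv"
            write_similarity_csv(S, p)
            written.append(p)

        rat = relative_active_time(bin_act) if bin_act is not None else None

        for method, S in matrices.items():
            for con in cfg.construction:
                con = dict(con)
                kind = con.pop("method")
                if kind == "fixed_threshold":
                    net = fixed_threshold_network(S, con.get("sc_th", 0.8), coords=rec.coords)
                elif kind == "fixed_kavg":
                    net = fixed_kavg_network(
                        S, con.get("target_kavg", 8.0), con.get("tol", 0.1), coords=rec.coords
                    )
                else:
                    net = multilayer_mst_network(S, con.get("n_layers", 4), coords=rec.coords)
                name = f"{band}_{method}_{kind}"
                networks[name] = net

                p = out / f"edges_{name}.csv"
                write_edge_list(net, p, S=S)
                written.extend([p, p.with_suffix(".json")])

                m = compute_metrics(net, **met_opts)
                record = m.to_dict()
                record.update(band=band, similarity=method, construction=kind,
                              threshold_used=net.construction.get("threshold_used"))
                if rat is not None:
                    from .metrics import degree_activity_relation

                    table, r = degree_activity_relation(
                        net, rat, n_bins=int(cfg.metrics.get("n_bins", 10))
                    )
                    record["degree_activity_r"] = None if np.isnan(r) else r
                p = out / f"metrics_{name}.json"
                p.write_text(json.dumps(record, indent=1))
                written.append(p)

    if cfg.geometric is not None and rec.coords is not None:
        geo = geometric_network(
            rec.coords,
            cell_ids=rec.cell_ids,
            mode=cfg.geometric.get("mode", "target_kavg"),
            value=float(cfg.geometric.get("value", 8.0)),
        )
        networks["geometric"] = geo
        p = out / "edges_geometric.csv"
        write_edge_list(geo, p)
        written.extend([p, p.with_suffix(".json")])

    if cfg.compare and len(networks) > 1:
        names = sorted(networks)
        nsi_mat = {a: {b: (1.0 if a == b else nsi(networks[a], networks[b])) for b in names} for a in names}
        reports = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                reports[f"{a}|{b}"] = compare_networks(
                    networks[a], networks[b], hub_fraction
                ).to_dict()
        p = out / "comparisons.json"
        p.write_text(json.dumps({"nsi_matrix": nsi_mat, "reports": reports}, indent=1))
        written.append(p)

    manifest = {
        "isletnet_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.canonical_hash(),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
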