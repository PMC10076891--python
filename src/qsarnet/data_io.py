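"""File I/O: descriptor CSVs, XML run configuration, model persistence, logging.

CSV dialect: UTF-8, comma separated, mandatory header, first column
``compound_id``. Missing values are rejected by default (the washing steps
assume a complete matrix); an optional mean-imputation flag is available.

The run configuration is an XML document with a fixed schema (see
:func:`parse_run_config`). Unknown elements are hard errors — a silently
ignored typo in a parameter name would corrupt an experiment.

Models are persisted as JSON text with every float stored as its full
``repr`` string, so a save/load round trip is bit-exact and the file stays
diffable and language-neutral.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError
from .table import DescriptorTable

logger = logging.getLogger("qsarnet")

MODEL_FORMAT = "qsarnet-model"
MODEL_VERSION = 1


def setup_logging(logfile: str | None = None, level: int = logging.INFO) -> None:
    """Timestamped logging to stderr, plus an optional logfile."""
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


# --------------------------------------------------------------------- tables
def read_descriptor_table(
    path: str | Path,
    activity_column: str,
    exclude_columns: tuple[str, ...] = (),
    impute_mean: bool = False,
) -> DescriptorTable:
    """Read a descriptor CSV into a :class:`DescriptorTable`.

    Row and column order are preserved. ``exclude_columns`` drops named
    non-descriptor metadata columns (e.g. SMILES strings) before validation.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "compound_id":
        raise ParseError(
            f"{path}: first column must be 'compound_id', got {df.columns[0]!r}"
        )
    if activity_column not in df.columns:
        raise ConfigError(f"{path}: activity column {activity_column!r} not found")
    ids = df["compound_id"].tolist()
    df = df.drop(columns=["compound_id", *[c for c in exclude_columns if c in df]])
    numeric = {}
    for col in df.columns:
        raw = df[col].to_numpy()
        try:
            # numpy's parser is correctly rounded, unlike pandas' fast path
            vals = raw.astype(np.float64)
        except ValueError:
            parsed = np.empty(len(raw))
            bad_row = -1
            for i, cell in enumerate(raw):
                try:
                    parsed[i] = float(cell)
                except ValueError:
                    parsed[i] = np.nan
                    if bad_row < 0:
                        bad_row = i
            if impute_mean and col != activity_column:
                mean = np.nanmean(parsed)
                vals = np.where(np.isnan(parsed), mean, parsed)
            else:
                raise ParseError(
                    f"{path}: non-numeric value {raw[bad_row]!r} at "
                    f"row {bad_row + 2} (compound {ids[bad_row]!r}), "
                    f"column {col!r}"
                ) from None
        numeric[col] = vals
    activity = numeric.pop(activity_column)
    desc = pd.DataFrame(numeric, index=pd.Index(ids, name="compound_id"))
    return DescriptorTable(
        desc, pd.Series(activity, index=desc.index, name=activity_column),
        activity_name=activity_column,
    )


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    """Write a descriptor table to CSV (inverse of :func:`read_descriptor_table`)."""
    df = table.descriptors.copy()
    df[table.activity_name] = table.activity
    df.index.name = "compound_id"
    df.to_csv(path, float_format="%.17g")


def read_fingerprints(path: str | Path) -> pd.DataFrame:
    """Read a binary fingerprint CSV (same shape as a descriptor CSV, 0/1 cells)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    df = pd.read_csv(path, index_col="compound_id")
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError(f"{path}: fingerprint cells must be 0 or 1")
    return df.astype(int)


# --------------------------------------------------------------------- config
@dataclass
class WashConfig:
    corr_threshold: float = 0.95
    sigma: float = 3.0
    min_neighbors: int = 10
    radius_quantile: float = 0.10
    normalization: str = "zscore"


@dataclass
class SplitConfig:
    test_fraction: float = 0.2


@dataclass
class NetworkConfig:
    hidden_layers: tuple[int, ...] = (20, 20, 20)
    dropout: float = 0.1
    lam: float = 1e-4
    learning_rate: float = 0.1
    batch_size: int = 16
    max_epochs: int = 2000
    eval_interval: int = 10
    patience: int = 20
    use_bias: bool = True


@dataclass
class VarSelectConfig:
    k: int = 5
    strategy: str = "exhaustive"
    max_evals: int = 10000
    q2_threshold: float = 0.60
    r2_threshold: float = 0.55


@dataclass
class RunConfig:
    wash: WashConfig = field(default_factory=WashConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    varselect: VarSelectConfig = field(default_factory=VarSelectConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        w, s, n, v = self.wash, self.split, self.network, self.varselect
        if not (0 < w.corr_threshold <= 1):
            raise ConfigError("wash/corr_threshold must be in (0, 1]")
        if w.sigma <= 0:
            raise ConfigError("wash/sigma must be > 0")
        if w.min_neighbors < 0:
            raise ConfigError("wash/min_neighbors must be >= 0")
        if not (0 < w.radius_quantile <= 1):
            raise ConfigError("wash/radius_quantile must be in (0, 1]")
        if w.normalization not in ("zscore", "minmax"):
            raise ConfigError("wash/normalization must be 'zscore' or 'minmax'")
        if not (0 < s.test_fraction < 1):
            raise ConfigError("split/test_fraction must be in (0, 1)")
        if not n.hidden_layers or any(h <= 0 for h in n.hidden_layers):
            raise ConfigError("network/hidden_layers must be positive integers")
        if not (0 <= n.dropout < 1):
            raise ConfigError("network/dropout must be in [0, 1)")
        if n.lam < 0:
            raise ConfigError("network/lambda must be >= 0")
        if n.learning_rate <= 0:
            raise ConfigError("network/learning_rate must be > 0")
        for name in ("batch_size", "max_epochs", "eval_interval"):
            if getattr(n, name) <= 0:
                raise ConfigError(f"network/{name} must be a positive integer")
        if n.patience < 0:
            raise ConfigError("network/patience must be >= 0")
        if v.k <= 0:
            raise ConfigError("varselect/k must be a positive integer")
        if v.strategy not in ("exhaustive", "random"):
            raise ConfigError("varselect/strategy must be 'exhaustive' or 'random'")
        if v.max_evals <= 0:
            raise ConfigError("varselect/max_evals must be a positive integer")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"]["hidden_layers"] = list(self.network.hidden_layers)
        return d


_SCHEMA: dict[str, dict[str, type]] = {
    "wash": {
        "corr_threshold": float, "sigma": float, "min_neighbors": int,
        "radius_quantile": float, "normalization": str,
    },
    "split": {"test_fraction": float},
    "network": {
        "hidden_layers": str, "dropout": float, "lambda": float,
        "learning_rate": float, "batch_size": int, "max_epochs": int,
        "eval_interval": int, "patience": int, "use_bias": bool,
    },
    "varselect": {
        "k": int, "strategy": str, "max_evals": int,
        "q2_threshold": float, "r2_threshold": float,
    },
}
# XML element name -> dataclass attribute where they differ
_RENAME = {"lambda": "lam"}


def _convert(text: str, typ: type, where: str):
    text = text.strip()
    try:
        if typ is bool:
            if text.lower() in ("true", "1", "yes"):
                return True
            if text.lower() in ("false", "0", "no"):
                return False
            raise ValueError(text)
        if typ is int:
            return int(text)
        if typ is float:
            return float(text)
        return text
    except ValueError as exc:
        raise ConfigError(f"element {where!r}: cannot parse {text!r}") from exc


def parse_run_config(path: str | Path) -> RunConfig:
    """Parse an XML parameter file into a validated :class:`RunConfig`.

    Schema: root ``<javadl>`` with optional children ``wash``, ``split``,
    ``network``, ``varselect`` and ``seed``. Every absent element takes its
    documented default; unknown elements are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file does not exist: {path}")
    try:
        root = ElementTree.parse(path).getroot()
    except ElementTree.ParseError as exc:
        raise ConfigError(f"{path}: malformed XML: {exc}") from exc
    if root.tag != "javadl":
        raise ConfigError(f"{path}: root element must be <javadl>, got <{root.tag}>")
    cfg = RunConfig()
    for section in root:
        if section.tag == "seed":
            cfg.seed = _convert(section.text or "", int, "seed")
            continue
        if section.tag not in _SCHEMA:
            raise ConfigError(f"{path}: unknown element <{section.tag}>")
        fields = _SCHEMA[section.tag]
        target = getattr(cfg, section.tag)
        for el in section:
            if el.tag not in fields:
                raise ConfigError(
                    f"{path}: unknown element <{el.tag}> in <{section.tag}>"
                )
            where = f"{section.tag}/{el.tag}"
            if el.tag == "hidden_layers":
                try:
                    layers = tuple(int(x) for x in (el.text or "").split(","))
                except ValueError as exc:
                    raise ConfigError(f"element {where!r}: bad layer list") from exc
                target.hidden_layers = layers
            else:
                attr = _RENAME.get(el.tag, el.tag)
                setattr(target, attr, _convert(el.text or "", fields[el.tag], where))
    return cfg.validate()


def write_run_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig back to the XML schema read by parse_run_config."""
    root = ElementTree.Element("javadl")
    inverse = {v: k for k, v in _RENAME.items()}
    for section in ("wash", "split", "network", "varselect"):
        sec_el = ElementTree.SubElement(root, section)
        for attr, val in asdict(getattr(cfg, section)).items():
            tag = inverse.get(attr, attr)
            el = ElementTree.SubElement(sec_el, tag)
            if attr == "hidden_layers":
                el.text = ",".join(str(h) for h in val)
            elif isinstance(val, bool):
                el.text = "true" if val else "false"
            else:
                el.text = repr(val) if isinstance(val, float) else str(val)
    ElementTree.SubElement(root, "seed").text = str(cfg.seed)
    tree = ElementTree.ElementTree(root)
    ElementTree.indent(tree)
    tree.write(path, encoding="unicode")


# --------------------------------------------------------------------- models
def _floats_out(arr: np.ndarray) -> list:
    """Nested lists of repr() strings — exact decimal round trip."""
    if arr.ndim == 1:
        return [repr(float(v)) for v in arr]
    return [_floats_out(row) for row in arr]


def _floats_in(nested) -> np.ndarray:
    return np.asarray(nested, dtype=float)


def save_model(model, path: str | Path) -> None:
    """Persist a trained model (network + preprocessing state) as JSON text."""
    from .network import TrainedModel  # local import avoids a cycle at import time

    if not isinstance(model, TrainedModel):
        raise ValidationError("save_model expects a TrainedModel")
    p = model.params
    norm = model.normalization
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "layer_sizes": list(p.layer_sizes),
        "activation": p.activation,
        "use_bias": p.biases is not None,
        "weights": [_floats_out(W) for W in p.weights],
        "biases": None if p.biases is None else [_floats_out(b) for b in p.biases],
        "normalization": None if norm is None else {
            "mode": norm.mode,
            "columns": norm.columns,
            "location": _floats_out(np.asarray(norm.location)),
            "scale": _floats_out(np.asarray(norm.scale)),
        },
        "descriptor_names": list(model.descriptor_names),
        "activity_name": model.activity_name,
        "activity_location": repr(float(model.activity_location)),
        "activity_scale": repr(float(model.activity_scale)),
        "config": model.config,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; bit-exact weight recovery."""
    from .network import NetworkParameters, TrainedModel
    from .wash import NormalizationParams

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"model file does not exist: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: truncated or corrupt model file: {exc}") from exc
    if doc.get("format") != MODEL_FORMAT:
        raise ParseError(f"{path}: not a {MODEL_FORMAT} file")
    if doc.get("version") != MODEL_VERSION:
        raise ParseError(
            f"{path}: model version {doc.get('version')!r} not supported "
            f"(expected {MODEL_VERSION})"
        )
    params = NetworkParameters(
        layer_sizes=tuple(doc["layer_sizes"]),
        weights=[_floats_in(W) for W in doc["weights"]],
        biases=None if doc["biases"] is None
        else [_floats_in(b) for b in doc["biases"]],
        activation=doc["activation"],
    )
    norm = None
    if doc["normalization"] is not None:
        nd = doc["normalization"]
        norm = NormalizationParams(
            mode=nd["mode"],
            columns=list(nd["columns"]),
            location=_floats_in(nd["location"]),
            scale=_floats_in(nd["scale"]),
        )
    return TrainedModel(
        params=params,
        normalization=norm,
        descriptor_names=list(doc["descriptor_names"]),
        activity_name=doc["activity_name"],
        config=doc["config"],
        activity_location=float(doc.get("activity_location", 0.0)),
        activity_scale=float(doc.get("activity_scale", 1.0)),
    )
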