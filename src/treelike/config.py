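"""Plain-text configuration: model parameters and partition definitions.

The config is a YAML mapping.  Top-level keys set the default model;
``partitions`` names the subsets with 1-based inclusive site ranges
(the convention of partition files in phylogenetics programs), with
optional per-subset overrides::

    model: hky
    kappa: 2.0
    frequencies: [0.3, 0.2, 0.2, 0.3]
    alpha: 0.5
    categories: 4
    partitions:
      gene1: 1-450
      gene2: {sites: 451-900, kappa: 3.5, rate: 1.4}

Internally site ranges become 0-based half-open; ``rate`` is a
subset-relative rate multiplier on branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ValidationError
from .model import RateCategories, SubstitutionModel, build_model, discretize_gamma

__all__ = ["AnalysisConfig", "SubsetSpec", "load_config", "parse_site_range"]


def parse_site_range(text: str) -> tuple[int, int]:
    """\"1-450\" (1-based inclusive) -> (0, 450) (0-based half-open)."""
    text = str(text).strip()
    if "-" in text:
        lo, hi = text.split("-", 1)
    else:
        lo = hi = text
    try:
        start, end = int(lo), int(hi)
    except ValueError:
        raise ValidationError(f"bad site range {text!r}") from None
    if start < 1 or end < start:
        raise ValidationError(f"bad site range {text!r}")
    return start - 1, end


@dataclass
class SubsetSpec:
    """One partition-defined subset and its model."""

    name: str
    sites: tuple[int, int]  # 0-based half-open
    model_name: str = "hky"
    kappa: float = 2.0
    exchangeabilities: list | None = None
    frequencies: list | None = None
    relative_rate: float = 1.0

    def build(self) -> SubstitutionModel:
        freqs = self.frequencies if self.frequencies is not None else [0.25] * 4
        return build_model(
            self.model_name,
            freqs,
            kappa=self.kappa,
            exchangeabilities=self.exchangeabilities,
        )


@dataclass
class AnalysisConfig:
    """Fully resolved analysis settings."""

    subsets: list[SubsetSpec]
    alpha: float | None = None
    categories: int = 1
    extras: dict = field(default_factory=dict)

    def rate_categories(self) -> RateCategories:
        if self.alpha is None:
            return discretize_gamma(1.0, 1) if self.categories == 1 else RateCategories(
                np.ones(self.categories), np.full(self.categories, 1.0 / self.categories)
            )
        return discretize_gamma(self.alpha, self.categories)

    def subset_map(self, site_count: int) -> np.ndarray:
        """Subset index per site; every site must be covered exactly once."""
        out = np.full(site_count, -1, dtype=int)
        for k, spec in enumerate(self.subsets):
            start, end = spec.sites
            if end > site_count:
                raise ValidationError(
                    f"subset {spec.name!r} range exceeds alignment length {site_count}"
                )
            if np.any(out[start:end] >= 0):
                raise ValidationError(f"subset {spec.name!r} overlaps another subset")
            out[start:end] = k
        if np.any(out < 0):
            missing = int(np.where(out < 0)[0][0]) + 1
            raise ValidationError(f"site {missing} is not assigned to any subset")
        return out


def load_config(path_or_dict) -> AnalysisConfig:
    """Read the YAML config (path, YAML text, or an already-parsed dict)."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = str(path_or_dict)
        if "\n" not in text and ":" not in text:
            with open(text) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")

    defaults = {
        "model": raw.get("model", "hky"),
        "kappa": raw.get("kappa", 2.0),
        "exchangeabilities": raw.get("exchangeabilities"),
        "frequencies": raw.get("frequencies"),
    }
    alpha = raw.get("alpha")
    categories = int(raw.get("categories", 1 if alpha is None else 4))

    partitions = raw.get("partitions")
    subsets: list[SubsetSpec] = []
    if partitions:
        for name, value in partitions.items():
            if isinstance(value, dict):
                sites = parse_site_range(value.get("sites", value.get("range", "")))
                spec = SubsetSpec(
                    name=name,
                    sites=sites,
                    model_name=value.get("model", defaults["model"]),
                    kappa=float(value.get("kappa", defaults["kappa"])),
                    exchangeabilities=value.get(
                        "exchangeabilities", defaults["exchangeabilities"]
                    ),
                    frequencies=value.get("frequencies", defaults["frequencies"]),
                    relative_rate=float(value.get("rate", 1.0)),
                )
            else:
                spec = SubsetSpec(
                    name=name,
                    sites=parse_site_range(value),
                    model_name=defaults["model"],
                    kappa=float(defaults["kappa"]),
                    exchangeabilities=defaults["exchangeabilities"],
                    frequencies=defaults["frequencies"],
                )
            subsets.append(spec)
    else:
        subsets.append(
            SubsetSpec(
                name="all",
                sites=(0, 0),  # resolved against the alignment at use time
                model_name=defaults["model"],
                kappa=float(defaults["kappa"]),
                exchangeabilities=defaults["exchangeabilities"],
                frequencies=defaults["frequencies"],
            )
        )
    known = {"model", "kappa", "exchangeabilities", "frequencies", "alpha",
             "categories", "partitions"}
    extras = {k: v for k, v in raw.items() if k not in known}
    return AnalysisConfig(subsets=subsets, alpha=alpha, categories=categories,
                          extras=extras)
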