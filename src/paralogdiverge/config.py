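"""Run configuration and logging.

A run is configured by a flat YAML mapping; every threshold used by the
analyses has a default here so a config file only needs to override what
it changes.  The seed is mandatory for stochastic stages and is written
to the log of every run.
"""

from __future__ import annotations

import logging

import yaml

DEFAULTS: dict = {
    "seed": 0,
    # relative-rate normalization
    "min_support": 5,
    "min_branches": 10,
    # specificity scoring
    "mr_cut": 0.8,
    "sh_cut": 0.5,
    "iterations": 10_000,
    "max_group_gap_frac": 0.5,
    "block_gap": 15,
    # multiple testing
    "q": 0.05,
}


def load_config(path=None) -> dict:
    """Merge a YAML config file over the package defaults."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg.update(user)
    return cfg


def setup_logging(log_path=None, seed=None) -> logging.Logger:
    logger = logging.getLogger("paralogdiverge")
    logger.setLevel(logging.INFO)
    if log_path is not None:
        handler = logging.FileHandler(log_path)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    if seed is not None:
        logger.info("run seed: %d", seed)
    return logger
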