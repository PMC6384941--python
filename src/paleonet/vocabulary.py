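"""Controlled vocabularies for occurrence validation.

The default vocabulary ships with the package as a YAML file (a constructed
stand-in with the documented category counts; see the file header). Users can
point :func:`load_vocabulary` at their own file with the same keys.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

_DEFAULT_RESOURCE = "synthetic_default_vocabulary.yaml"

REQUIRED_KEYS = (
    "preservational_modes",
    "paleoenvironments",
    "morphogroups",
    "trace_architectures",
    "form_categories",
    "paleocommunities",
    "taxon_flags",
)


def load_vocabulary(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load a controlled vocabulary mapping from YAML.

    Parameters
    ----------
    path
        Optional path to a user vocabulary file. When omitted, the packaged
        default is used.

    Returns
    -------
    dict mapping each vocabulary name to an ordered list of codes. The
    ``paleoenvironments`` list is ordered shallow to deep.
    """
    if path is None:
        text = (
            resources.files("paleonet").joinpath(_DEFAULT_RESOURCE).read_text()
        )
    else:
        text = Path(path).read_text()
    vocab = yaml.safe_load(text)
    missing = [k for k in REQUIRED_KEYS if k not in vocab]
    if missing:
        raise KeyError(f"vocabulary file lacks keys: {missing}")
    return {k: list(v) for k, v in vocab.items()}
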