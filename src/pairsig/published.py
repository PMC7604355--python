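"""Bundled published signatures.

``irgp23_os`` is the published 23-pair immune-related gene-pair (IRGP)
overall-survival signature for cutaneous melanoma: 23 ordered gene pairs over
39 unique immune genes, LASSO-Cox coefficients, and the published fixed
risk-score cutoff of -0.674 (derived from the 5-year time-dependent ROC).

``irgp_obs`` is the companion observed-survival-interval (OBS) variant. Its
published record consists of the cutoff (-1.433) and endpoint only — the pair
list and coefficients were never printed — so it ships as cutoff metadata and
refuses to score until the user supplies entries.
"""

from __future__ import annotations

from importlib import resources

from .datatypes import PrognosticSignature
from .io import read_signature

__all__ = ["load_published_signature", "load_bundled_gene_list", "PUBLISHED_SIGNATURES"]

PUBLISHED_SIGNATURES = ("irgp23_os", "irgp_obs")


def _data_path(name: str):
    return resources.files("pairsig.data").joinpath(name)


def load_published_signature(name: str) -> PrognosticSignature:
    """Return a bundled signature by name (``irgp23_os`` or ``irgp_obs``)."""
    if name == "irgp23_os":
        with resources.as_file(_data_path("irgp23_os.tsv")) as p:
            return read_signature(p)
    if name == "irgp_obs":
        return PrognosticSignature(
            entries=[],
            cutoff=-1.433,
            cutoff_strategy="fixed",
            endpoint_name="OBS",
            name="irgp_obs",
        )
    raise KeyError(
        f"unknown published signature {name!r}; available: {', '.join(PUBLISHED_SIGNATURES)}"
    )


def load_bundled_gene_list() -> list[str]:
    """The 39 unique gene symbols of the bundled 23-pair signature."""
    text = _data_path("signature_genes.txt").read_text()
    return [line.strip().upper() for line in text.splitlines() if line.strip()]
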