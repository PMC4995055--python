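"""mitokit: comparative analytics for annotated mitochondrial genomes.

Annotation-table analytics (sizes, spacers/overlaps, strand census), base
composition and strand skews, codon usage and RSCU under the invertebrate
mitochondrial code, Nei–Gojobori Ka/Ks, gene-order breakpoint comparison,
control-region structural dissection, and a deterministic synthetic
mitogenome generator for ground-truth testing.
"""

__version__ = "0.1.0"

from importlib import resources
from pathlib import Path


def packaged_annotation_path() -> Path:
    """Path to the packaged whitefly (Aleurocanthus spiniferus) annotation
    table, the worked example used throughout the documentation."""
    return Path(str(resources.files("mitokit.data").joinpath("spiniferus_annotation.tsv")))
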