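import numpy as np
import pandas as pd
import pytest

from bandscape.datatypes import (
    CohortBundle,
    CohortTable,
    GeneCNMatrix,
    GenomeAnnotation,
    MutationTable,
)


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Two chromosomes, two bands each, two genes per band."""
    bands = pd.DataFrame(
        [
            ("chr1", 0, 100, "1p1", "gneg"),
            ("chr1", 100, 200, "1q1", "gpos"),
            ("chr13", 0, 100, "13q14.2", "gneg"),
            ("chr13", 100, 200, "13q14.3", "gpos"),
        ],
        columns=["chrom", "start", "end", "band_name", "stain"],
    )
    genes = pd.DataFrame(
        [
            ("A1", "chr1", 10, 30),
            ("A2", "chr1", 40, 60),
            ("B1", "chr1", 110, 130),
            ("B2", "chr1", 140, 160),
            ("RB1", "chr13", 10, 30),
            ("C2", "chr13", 40, 60),
            ("D1", "chr13", 110, 130),
            ("D2", "chr13", 140, 160),
        ],
        columns=["gene_id", "chrom", "start", "end"],
    )
    return GenomeAnnotation(genes=genes, bands=bands)


def make_bundle(annotation: GenomeAnnotation, cn_values: np.ndarray, samples: list[str],
                mutations: pd.DataFrame | None = None) -> CohortBundle:
    genes = list(annotation.genes["gene_id"])
    cn = GeneCNMatrix(pd.DataFrame(cn_values, index=genes, columns=samples))
    if mutations is None:
        mutations = pd.DataFrame(
            columns=["sample_id", "gene_id", "mutation_class", "pathogenic"]
        )
    clinical = CohortTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "pam50": ["LumA"] * len(samples),
                "er": ["ER+"] * len(samples),
                "her2": ["HER2-"] * len(samples),
                "os_months": np.linspace(10, 60, len(samples)),
                "os_event": [1] * len(samples),
            }
        )
    )
    return CohortBundle(
        cn=cn,
        mutations=MutationTable(mutations),
        clinical=clinical,
        annotation=annotation,
    )


@pytest.fixture
def tiny_bundle(tiny_annotation) -> CohortBundle:
    samples = [f"S{i}" for i in range(1, 11)]
    rng = np.random.default_rng(7)
    vals = rng.choice([-1, 0, 1], size=(8, 10), p=[0.3, 0.5, 0.2]).astype(float)
    muts = pd.DataFrame(
        [
            ("S1", "RB1", "nonsense", True),
            ("S2", "RB1", "nonsense", True),
            ("S3", "RB1", "missense", False),
        ],
        columns=["sample_id", "gene_id", "mutation_class", "pathogenic"],
    )
    return make_bundle(tiny_annotation, vals, samples, muts)
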