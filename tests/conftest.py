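"""Shared fixtures: small synthetic cohorts and published reference tables."""

import numpy as np
import pandas as pd
import pytest

import crosspath as cp

TISSUES3 = ("Adipose", "Islet", "Liver")


@pytest.fixture(scope="session")
def small_db():
    return cp.generate_pathway_db(n_pathways=12, size_range=(5, 10), n_genes=150,
                                  link_density=0.2, seed=11)


@pytest.fixture(scope="session")
def small_gnet(small_db):
    return cp.generate_gene_network(small_db, within_prob=0.5, cross_prob=0.01,
                                    seed=12)


@pytest.fixture(scope="session")
def design3():
    return cp.CohortDesign(tissues=TISSUES3)


@pytest.fixture(scope="session")
def null_data(small_db, small_gnet, design3):
    """Pure-noise cohort: no planted structure anywhere."""
    gt = cp.null_ground_truth()
    exprs = cp.generate_expression(small_db, small_gnet, design3, gt, seed=13)
    pci = cp.pci_matrix(exprs, small_db, small_gnet)
    traits = cp.generate_traits(design3, pci, gt, seed=14)
    return exprs, pci, traits, gt


@pytest.fixture(scope="session")
def planted_data(small_db, small_gnet, design3):
    """Cohort with one co-active pathway pair and per-trait planted effects."""
    gt = cp.make_ground_truth(small_db, tissues=TISSUES3, n_coactive_groups=1,
                              group_size=2, effect=1.0, noise_sd=0.2,
                              activity_sd=1.0, seed=15)
    exprs = cp.generate_expression(small_db, small_gnet, design3, gt, seed=16)
    pci = cp.pci_matrix(exprs, small_db, small_gnet)
    traits = cp.generate_traits(design3, pci, gt, seed=17)
    return exprs, pci, traits, gt


# Reference summary tables from the published mouse multi-tissue T2D study
# the synthetic cohort emulates. Cells only; the margins (row totals,
# per-tissue totals, per-group means) are what the reporting layer must
# reproduce from them.

STUDY_TISSUES = ("Adipose", "Gastrocnemius", "Hypothalamus", "Islet", "Liver",
                 "Soleus")


@pytest.fixture(scope="session")
def published_linking_cells():
    cells = {
        "TG": (40, 6, 5, 25, 25, 5),
        "glucose": (5, 2, 3, 11, 9, 1),
        "Adiponectin": (1, 1, 0, 2, 4, 0),
        "Resistin": (22, 7, 1, 8, 9, 6),
        "PAI1": (10, 1, 2, 3, 5, 2),
        "Insulin": (51, 11, 5, 43, 61, 6),
        "weight": (63, 14, 14, 32, 47, 15),
        "islets": (4, 2, 0, 6, 4, 0),
    }
    return pd.DataFrame.from_dict(cells, orient="index",
                                  columns=list(STUDY_TISSUES))


PUBLISHED_LINKING_ROW_TOTALS = {
    "TG": 106, "glucose": 31, "Adiponectin": 8, "Resistin": 53, "PAI1": 23,
    "Insulin": 177, "weight": 185, "islets": 16,
}
PUBLISHED_LINKING_TISSUE_TOTALS = (196, 44, 30, 130, 164, 35)
PUBLISHED_LINKING_GRAND_TOTAL = 599


@pytest.fixture(scope="session")
def published_group_cells():
    groups = ("B6-ob-4wk", "B6-ob-10wk", "B6-lean-4wk", "B6-lean-10wk",
              "BTBR-ob-4wk", "BTBR-ob-10wk", "BTBR-lean-4wk", "BTBR-lean-10wk")
    rows = {
        "Adiponectin": (233, 0, 0, 0, 145, 277, 0, 152),
        "glucose": (295, 147, 189, 211, 270, 229, 142, 0),
        "Insulin": (346, 155, 101, 193, 239, 151, 187, 207),
        "islets": (170, 0, 0, 0, 67, 159, 0, 0),
        "Leptin": (257, 179, 167, 196, 259, 197, 121, 243),
        "Resistin": (250, 0, 0, 0, 95, 178, 0, 0),
        "TG": (323, 165, 139, 211, 231, 228, 175, 186),
        "weight": (193, 176, 183, 288, 198, 265, 211, 197),
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(groups))


PUBLISHED_GROUP_MEANS = (258.4, 102.8, 97.4, 137.4, 188.0, 210.5, 104.5, 123.1)


def naive_pci(h, adj, include_diagonal=True, normalize="size"):
    """Brute-force double-loop PCI for one animal (test oracle)."""
    n = len(h)
    total = 0.0
    for i in range(n):
        for j in range(i, n):
            if i == j:
                if not include_diagonal:
                    continue
                a = 1.0
            else:
                a = adj[i][j]
            total += np.sign(h[i] + h[j]) * np.sqrt(abs(h[i])) * a * np.sqrt(abs(h[j]))
    if normalize == "size":
        denom = n
    else:
        denom = n * (n + 1) / 2 if include_diagonal else max(n * (n - 1) / 2, 1)
    return total / denom
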