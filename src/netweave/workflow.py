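"""Convenience drivers for the full inference -> aggregation workflow."""

from __future__ import annotations

from .aggregate import AggregationResult, irp_aggregate
from .data import ExpressionMatrix, MethodNetwork
from .inference import (
    DPIParams,
    MIParams,
    TOMParams,
    TreeEnsembleParams,
    aracne_transform,
    clr_transform,
    infer_mi,
    infer_pcor,
    infer_pearson,
    infer_spearman,
    infer_tom,
    infer_tree_ensemble,
)

__all__ = ["METHOD_SUITE", "infer_suite", "community_network"]

METHOD_SUITE = [
    "pearson",
    "spearman",
    "pcor",
    "tom",
    "mi",
    "clr",
    "aracne",
    "tree_ensemble",
]


def infer_suite(
    em: ExpressionMatrix,
    methods: list[str] | None = None,
    mi_params: MIParams | None = None,
    tom_params: TOMParams | None = None,
    dpi_params: DPIParams | None = None,
    tree_params: TreeEnsembleParams | None = None,
) -> list[MethodNetwork]:
    """Run the implemented inference methods on one expression matrix.

    The raw MI network is computed once and reused for the CLR and DPI
    post-processed variants.  Methods that standardise internally (partial
    correlation, the tree ensemble) do so themselves; the others consume the
    matrix as given.
    """
    methods = list(methods or METHOD_SUITE)
    unknown = set(methods) - set(METHOD_SUITE)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    nets: list[MethodNetwork] = []
    mi_net = None
    if {"mi", "clr", "aracne"} & set(methods):
        mi_net = infer_mi(em, mi_params)
    for name in methods:
        if name == "pearson":
            nets.append(infer_pearson(em))
        elif name == "spearman":
            nets.append(infer_spearman(em))
        elif name == "pcor":
            nets.append(infer_pcor(em))
        elif name == "tom":
            nets.append(infer_tom(em, tom_params))
        elif name == "mi":
            nets.append(mi_net)
        elif name == "clr":
            nets.append(clr_transform(mi_net))
        elif name == "aracne":
            nets.append(aracne_transform(mi_net, dpi_params))
        elif name == "tree_ensemble":
            nets.append(infer_tree_ensemble(em, tree_params))
    return nets


def community_network(nets: list[MethodNetwork]) -> AggregationResult:
    """Alias for inverse-rank-product aggregation of a method suite."""
    return irp_aggregate(nets)
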