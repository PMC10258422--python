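import numpy as np
import pytest

from netweave import (
    TreeEnsembleParams,
    generate_grn,
    grn_to_gold_standard,
    infer_suite,
    irp_aggregate,
    nc_backbone,
    prune_delta,
    roc_pr,
    simulate_expression,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_pipeline():
    """Full pipeline on the desk-scale synthetic benchmark, 3 replicates.

    60 genes, 10 regulators, mean out-degree 3, 400 samples, noise s.d. 0.5;
    the tree ensemble runs at 100 trees (the package's desk-scale setting).
    Shared across evaluation tests because it is the expensive part of the
    suite.
    """
    reps = []
    for seed in (0, 1, 2):
        grn = generate_grn(60, 10, 3, seed)
        em = simulate_expression(grn, 400, 0.5, seed + 100)
        std = grn_to_gold_standard(grn)
        nets = infer_suite(em, tree_params=TreeEnsembleParams(n_trees=100, seed=seed))
        aucs = {net.method_name: roc_pr(net, std).auc for net in nets}
        community = irp_aggregate(nets).table
        dense_curve = roc_pr(community, std)
        scores = nc_backbone(community.to_weighted())
        pruned = prune_delta(scores, 1.28)
        pruned_curve = roc_pr(pruned, std)
        reps.append(
            {
                "method_aucs": aucs,
                "dense": dense_curve,
                "pruned": pruned_curve,
                "n_pruned_edges": pruned.n_edges,
            }
        )
    return reps
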