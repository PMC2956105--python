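"""Representative train/test splitting with a Kohonen self-organizing map.

Compounds are clustered on a small map in standardized descriptor space;
from each occupied cell the compounds nearest the cell prototype go to
training, the farthest to test — so the test set stays inside the chemical
space spanned by the training set.
"""
import numpy as np

from erqsar import compute_matrix, load_fixture, split_by_cells, subsplit_validation, train_som
from erqsar.pls import autoscale

table = load_fixture()
matrix = compute_matrix(table)
Xs, _ = autoscale(matrix.values)

grid = train_som(Xs, (5, 5), seed=1)
print(f"trained a 5x5 Kohonen map: quantization error "
      f"{grid.initial_qe:.3f} (random init) -> {grid.final_qe:.3f} (trained)")

occupancy = np.bincount(grid.bmu(Xs), minlength=grid.n_cells).reshape(5, 5)
print("cell occupancy (compounds per map position):")
print(occupancy)

split = split_by_cells(grid, Xs, 61 / 82, seed=1, ids=matrix.compound_ids)
print(f"\nsplit: {len(split.train_ids)} training / {len(split.test_ids)} test compounds")

sub = subsplit_validation(split, (2, 1), seed=1)
print(f"2:1 sub-split for neural-network validation: "
      f"{len(sub.train_ids)} train / {len(sub.validation_ids)} validation")
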