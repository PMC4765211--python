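# vpsearch

Content-based similarity search for gene-expression profiles. Instead of
querying a repository by keyword or accession, you query it with an
expression profile and get back the most similar stored profiles.

The package provides:

* an HDF5 expression-database dialect (`Sample` / `Feature` / `Data`
  datasets, with `Data` stored features × samples as float64);
* optional PCA reduction of profiles to a low-dimensional search space
  (10 components by default), with queries projected by the database-fitted
  model;
* a **vantage-point tree** index supporting *exact* k-nearest-neighbor
  search with triangle-inequality pruning — results are always identical to
  a brute-force scan, only cheaper;
* a brute-force oracle and a KD-tree comparator, plus a hardware-independent
  scaling benchmark that counts distance evaluations instead of wall-clock;
* a deterministic synthetic-data generator producing clustered expression
  databases with planted cluster-crossing and outlier samples;
* a CLI with `build`, `search`, `simulate` and `benchmark` sub-commands.

## CLI usage

```sh
# generate a synthetic two-cluster database (50+50 samples, 200 features)
vpsearch simulate --output db.h5 --labels labels.csv --seed 17

# build an index: PCA to 10 components, then the vantage-point tree
vpsearch build --input db.h5 --output index.h5 --components 10 --seed 0

# query with a profile (HDF5 single-sample file or CSV); top 10 by default
vpsearch search --index index.h5 --query query.h5 --k 10 --format csv

# compare brute-force / KD-tree / vp-tree search cost
vpsearch benchmark --sizes 10,100,1000 --dim 10 --queries 100 --output bench.csv
```

Query CSV layouts: either two columns with a `feature,value` header, or a
single header row of feature ids followed by one row of values. Query
features are aligned to the database's feature order; extra features are
dropped with a warning, missing ones are an error.

`--exclude-self` drops a distance-0 hit carrying the query's own sample id,
for querying a database with one of its own records.

## Library usage

```python
import vpsearch as v

matrix, labels = v.generate(v.SyntheticSpec(seed=17))
index = v.IndexFile.build(matrix, n_components=10, seed=0)
query = v.prototype_query(matrix, labels, "cluster0")
result = index.search(query, k=10)
print(result.hits)              # [(sample_id, distance), ...] ascending
print(result.n_distance_evals)  # metric calls spent on this query
```

Indexes persist to a versioned HDF5 container (`save_index` / `load_index`)
and reload with bit-identical search behavior. Any distance function
satisfying the triangle inequality can be registered via
`register_metric(Metric(name, fn))` and selected at build time.

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(exactness vs. brute force over 500+ randomized instances, pruning
soundness audits, sub-linear scaling of distance evaluations, the
construction-cost bound, partition invariants, PCA correctness against an
eigendecomposition oracle, the two-cluster qualitative reproduction, and
file round-trips). `scripts/acceptance.py` recomputes the same properties
from scratch and writes the (empty — there are no numeric targets) JSON
report; it exits non-zero if any property fails.
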