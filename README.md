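# fpkit

Molecular fingerprint prediction from tandem mass spectra via Nyström
kernel embeddings.

MS/MS spectra are compared with a probability product kernel (domain
kernels, e.g. on fragmentation trees, can be supplied as precomputed
matrices and combined by weighted summation). The landmark kernel block is
eigendecomposed and turned into an explicit feature map (Nyström
approximation); on that embedding either a linear multi-label SVM (with
Platt-calibrated probabilities and a primal→dual export) or a deep neural
network is trained to predict binary substructure labels. Predicted
probabilistic fingerprints rank candidate structures in a database search.
A binned-spectrum DNN baseline, structure-disjoint evaluation tooling and a
synthetic benchmark generator are included.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: analytic
parameter-count checks, Nyström exactness/whitening properties, primal/dual
equivalence, metric oracle equivalence, an SGD-vs-QP SVM comparison, and
end-to-end recovery plus noise-robustness experiments on the calibrated
synthetic benchmark.

## CLI

```bash
fpkit fixtures --seed 7 --out bench/              # synthetic benchmark
fpkit preprocess --spectra in.mgf --out merged.mgf --weights w.tsv
fpkit noise --spectra merged.mgf --out noisy.mgf --seed 1 --drop 0.2
fpkit kernel --spectra merged.mgf --out K.h5 --sigma-m 0.01
fpkit embed --kernel K.h5 --projection P.h5 --out X.h5
fpkit train --embedding X.h5 --fingerprints fp.tsv --head deep-kernel \
            --seed 1 --out model.h5
fpkit predict --model model.h5 --embedding X.h5 --out pred.tsv
fpkit evaluate --pred pred.tsv --truth fp.tsv --micro-threshold 10
fpkit search --pred pred.tsv --candidates bench/candidates \
             --scoring loglik --topk 10 --out ranked.tsv
```

## Package layout

| module | contents |
| --- | --- |
| `fpkit.spectra_data` | spectrum/fingerprint data model, MGF/MSP IO, merging, replicate weights, label selection, binned/formula features, noise simulation |
| `fpkit.kernels` | probability product kernel, precomputed kernel IO, cosine normalization, weighted combination |
| `fpkit.nystrom` | landmark eigendecomposition, projection matrix, feature embedding, kernel reconstruction |
| `fpkit.models` | Nyström SVM (+Platt, +dual export), deep kernel DNN, spectrum DNN, parameter counting, serialization |
| `fpkit.evaluation` | MCC / BM / compound Tanimoto, micro averaging of rare labels, structure-disjoint folds |
| `fpkit.dbsearch` | log-likelihood and probabilistic Tanimoto candidate scoring, identification rate at k |
| `fpkit.synthetic_fixtures` | seeded benchmark generator (label-linked fragments, replicates, decoy candidate sets) |
| `fpkit.pipeline` | end-to-end orchestration shared by CLI, tests and the acceptance script |
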