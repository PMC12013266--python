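# promodiff

Diffusion-based design of bacterial promoter sequences with
transformer-based strength screening.

Promoters — the short DNA regions upstream of a transcription start site
(TSS) that recruit RNA polymerase — are a central engineering handle in
synthetic biology, but the sequence space (4^L for length L) is far too
large to search experimentally. `promodiff` implements a two-model design
loop for fixed-length upstream sequences:

1. **Generate.** A denoising diffusion probabilistic model (DDPM) is trained
   unsupervised on one-hot encoded natural promoters. The forward process
   corrupts a sequence matrix x₀ over T steps, x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε
   with ᾱ_t = ∏(1−β_s); a small convolutional network with timestep and
   positional conditioning learns to predict ε under an L1 loss, and
   ancestral sampling from pure noise followed by per-row argmax decoding
   yields novel promoter sequences.
2. **Screen.** A transformer encoder regressor predicts promoter strength
   from three aligned token streams (nucleotides 0–3, overlapping
   dinucleotides 4–23, positions 0…L−1). Strengths are preprocessed by
   X_log = log₁₀(X) followed by min–max normalization, and training
   minimizes w·MSE + w·(1 − PCC), combining scale fit with linear
   association. A one-hot CNN baseline shares the loss and evaluation path.
3. **Evaluate.** Generated sets are compared to natural sets by sliding
   window k-mer frequency spectra and their Pearson correlation (densified
   over all 4^k words), positional k-mer profiles, and sequence-logo
   information content. A saturation-mutagenesis scan scores every single
   base substitution of test promoters with the trained predictor and
   summarizes per-position sensitivity by mutation class (A↔T/C↔G swaps vs
   {A,T}↔{C,G} crossings).

Everything is testable offline: `promodiff.fixtures` generates seeded
synthetic corpora with planted −10 (TATAAT-like) and −35 (TTGACA-like)
elements over an AT-rich background and a known exponential strength law,
so every stage has recoverable ground truth. See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

```python
import promodiff as pm

# a seeded synthetic corpus: 2,000 promoters of 50 nt with planted motifs
dataset = pm.generate_fixture(pm.FixtureSpec(count=2000, seed=1))
train, test = pm.split_dataset(dataset, test_fraction=0.2, seed=0)

# train the generator and sample candidates
gen = pm.train_ddpm(dataset, pm.DiffusionConfig(T=200, epochs=100, batch_size=128, seed=0))
candidates = gen.sample(1000, seed=7)
print(round(pm.kmer_pcc(candidates, dataset.sequences, 2), 3))
# 0.975
print(pm.positional_profile(candidates, "TATAAT").peak())
# 38   (the planted TATAAT window starts at index 38, TSS position −12)

# train the strength predictor and screen the candidates
model = pm.train_predictor(train, pm.PredictorConfig(epochs=15, seed=0))
print(round(pm.evaluate_predictor(model, test), 3))
# 0.684
scores = model.predict(candidates)          # normalized strength scale
best = candidates[scores.argmax()]          # top-ranked synthetic promoter
```

The 2-mer correlation of 0.975 says the sampled sequences reproduce the
dinucleotide composition of the training corpus almost exactly; the profile
peak at index 38 says the generator placed the −10 element where the corpus
carries it; and the held-out PCC of 0.684 approaches the fixture's noise
ceiling (≈0.75), i.e. the transformer has recovered most of the learnable
sequence–strength signal.

The same workflow is available from the shell:

```bash
promodiff fixtures --count 2000 --seed 1 --out corpus.csv
promodiff generate --train corpus.csv --count 500 --steps 200 --epochs 100 --seed 0 --out generated.fasta
promodiff predict --train corpus.csv --test corpus.csv --arch transformer --seed 0 --out predictions.csv
promodiff evaluate --generated generated.fasta --natural corpus.csv --out-dir results/
promodiff run --config run.yaml        # full pipeline from a YAML config
```

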