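# brainmatch

Brain-image identity verification from structural T1 MRI: can a person be
recognized from the shape of their gray matter? `brainmatch` implements the
full verification pipeline — rigid registration to a tissue-prior template,
prior-guided mixture-model tissue segmentation, Otsu binarization of the
gray-matter probability map, template-bridged alignment of two binary
gray-matter volumes, directed 3D chamfer matching with linear score
normalization, and FAR/FRR/EER verification evaluation — together with a
seeded synthetic brain-phantom generator that provides multi-subject,
multi-visit cohorts with full ground truth.

It is aimed at researchers studying structural-MRI biometrics or anyone who
needs a compact, fully testable reference implementation of
prior-initialized EM tissue classification and alignment-based binary shape
matching.

## The method

**Registration.** Each image `I` is mapped to a template `T` by a
6-parameter rigid transform `M = Trans(p1,p2,p3)·Rx(p4)·Ry(p5)·Rz(p6)`
estimated by Gauss–Newton minimization of the sum of squared intensity
differences, after both volumes are smoothed with a 5 mm FWHM Gaussian.

**Segmentation.** Template-space tissue priors `P_T(k, x)` for
k ∈ {GM, WM, CSF, other} are pulled onto the image, `p_nk(0) = P_T(k, M⁻¹xₙ)`,
and refined by an iterative mixture-model update: per class, the effective
count `m_k = Σₙ p_nk`, weighted mean `μ_k`, and variance `σ_k` are
re-estimated; class-conditional normal densities
`g_nk = (2πσ_k)^{-1/2} exp(−(fₙ−μ_k)²/2σ_k)` are multiplied into the current
probabilities, `q_nk = g_nk·p_nk(t)`, and renormalized per voxel.

**Gray-matter structure.** The GM probability map is binarized at an Otsu
threshold (256 uniform bins on [0, 1]), giving a binary structure `B` that is
invariant to global intensity scaling between visits.

**Matching.** Two images are aligned through the template bridge,
`M12 = M1·M2⁻¹`, and compared by the directed chamfer distance

    d = Σ_x min_y { ‖x − y‖ : B1'(x) = 1, B2'(y) = 1 }   (mm)

evaluated exactly via the Euclidean distance transform of the reference
mask's complement. Scores are normalized to [0, 100] by
`s = (1 − (d − d_min)/(d_max − d_min))·100` with `(d_min, d_max)` obtained by
training; 100 means full matching, 0 mismatching.

**Evaluation.** All same-subject cross-visit pairs are genuine, all
cross-subject pairs imposter; FRR(t) is the fraction of genuine scores below
the threshold, FAR(t) the fraction of imposter scores at or above it, and
the EER is read off where the two curves cross.

## Worked example

```sh
brainmatch simulate --subjects 3 --visits 2 --seed 7 --out cohort/
brainmatch evaluate --cohort cohort/manifest.csv --out report/
```

which logs

```
INFO brainmatch: wrote 6 volumes to cohort/
INFO brainmatch: EER=0.0000; report in report/
report/summary.json
```

and `report/summary.json` contains

```json
{
  "dmax": 1578.9931086796919,
  "dmin": 678.25,
  "eer": 0.0,
  "genuine_mean": 97.93315909493055,
  "imposter_mean": 14.200166993583146,
  "n_genuine": 3,
  "n_imposter": 3
}
```

The three genuine pairs (same subject, different visits) score near 100, the
three imposter pairs far lower, and the step curves never cross: on this
small synthetic cohort verification is error-free. `report/` also holds the
per-pair score CSV, the threshold table (FAR/FRR/TAR per threshold), a score
histogram and a FAR-vs-FRR plot. The same computation is available from
Python via `brainmatch.generate_cohort`, `brainmatch.score_cohort`,
`brainmatch.rate_table`, and `brainmatch.equal_error_rate`.

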