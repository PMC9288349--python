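# Methods

## Model

A (2,2) visual secret sharing scheme encodes a binary secret image into
two binary shares such that the pixelwise AND of the shares (the
digital analogue of stacking transparencies) shows the secret, while
either share alone is statistically independent of it.  We use the
convention 0 = black, 1 = white throughout; writers map bits to display
intensities (0 → 0, 1 → 255) only at the file boundary.

Three schemes are implemented.

* **(2,2)-VCS** (noise shares): each secret pixel becomes a 2×2 tile of
  m = 4 subpixels per share.  White pixels use identical 2-black rows
  of the basis matrix S0; black pixels use complementary 2-black rows
  of S1.  Stacks carry 2 vs 4 black subpixels (contrast α = 1/2), and
  every share tile carries exactly 2 black subpixels regardless of the
  secret.
* **(2,2)-EVCS** (meaningful covers): the basis matrix `S^s_{c1 c2}`
  additionally encodes the two cover pixels — a share row carries 3
  black subpixels where its cover is black and 2 where it is white,
  and the stacked row carries 4 (secret black) or 3 (secret white)
  black subpixels (α = 1/4).  Two of the eight matrices are canonical
  (`S_bbb = [[0100],[1000]]`, `S_wbb = [[0100],[0100]]`); the other six
  are found once at import by exhaustive search over 4-bit pattern
  pairs under the same row/stack count constraints.  All eight
  combinations are feasible at m = 4.
* **EF-EVCS** (expansion-free): works on 2×2 blocks of the images
  themselves.  Secret and covers are independently halftoned onto
  restricted level sets (below); encryption rearranges each cover
  block's pixels so the share blocks AND to the secret block's level.
  Shares equal the secret's pixel dimensions exactly.

## Limited gray-level halftoning

`limited_halftone` tiles the (white-padded) image into non-overlapping
blocks and maps each block's mean intensity g to the allowed black
count nearest to the ideal darkness `s_b · (1 − g/255)`.  The printed
ideal is a real number; quantizing it onto a restricted level set is
what keeps every block encryptable.  Numerical choices:

* **Tie-break toward the darker level.**  Deterministic, and the reason
  a level-restricted reconstruction looks slightly darker than an
  unrestricted halftone.
* **Intra-block placement is uniform at random** among all
  C(s_b, count) arrangements.  Positions inside a block carry no tone
  information and are rewritten by encryption anyway; random placement
  avoids visible tiling artifacts in standalone halftones.
* **Padding** extends images to block multiples on the bottom/right
  with white; the original dimensions are recorded in the share
  metadata so viewers can crop back.
* The **error-diffusion baseline** is Floyd–Steinberg (7/16, 3/16,
  5/16, 1/16), raster scan, threshold 128 — the de-facto standard
  against which the limited halftoner's quality loss is judged.

With the full level set {0..s_b} the halftoner tracks the ideal
darkness to within half a level per block (tested).  With the default
secret set {3, 4} the output is darker but still legible — the price of
expansion-free encryption.

## Feasibility and the default level sets

Stacking can only darken: a stacked block's black count lies in
`[max(b1, b2), min(s_b, b1 + b2)]`.  A configuration
(secret_levels, cover_levels) is feasible iff every combination
(t, b1, b2) lies in that interval — e.g. a 3-black cover block can
never stack down to a 2-black secret block, which is why unrestricted
halftoning cannot be encrypted this way.  The interval rule is verified
in the tests against brute-force pattern search over all
(t, b1, b2) ∈ [0,4]³.

Defaults: secret {3, 4}, cover {2, 3} on 2×2 blocks.  This is the
unique pair of two-level sets that (a) is feasible for all
combinations, and (b) reproduces the classic EVCS subpixel counts, so
recovered blocks are interpreted as 4 → black / 3 → white and cover
blocks as 3 → black / 2 → white.  The 3-black count belongs to *both*
tables — white in a recovered image, black on a cover — so
interpretation is always context-dependent (`interpret_block`).  Both
level sets are configurable; `EfConfig.validate_feasible` rejects
infeasible choices up front.

## Encryption and security

For every block, the pattern pair (p1, p2) is drawn **uniformly from
all valid arrangements** for its (t, b1, b2) triple, not merely from
column permutations of one fixed matrix.  For the classic tile counts
the two samplers coincide (tested by enumerating all 4! permutations
of each basis matrix and comparing with the valid-pair family); in
general the valid-pair sampler maximizes per-block entropy.

Security rests on two facts, both checked exactly:

1. **Marginal uniformity.**  Within a cover level b, the pattern a
   single share shows is uniform over all C(s_b, b) patterns and
   independent of the secret level t.  `leakage_posterior` enumerates
   every encoding with `fractions.Fraction` weights and confirms the
   posterior P(secret black | observed pattern) equals the 1/2 prior
   for every observable pattern of every shipped scheme.  This is the
   package's central theorem-check; no sampling is involved.
2. **Preprocessing independence.**  The secret and covers are halftoned
   independently *before* encryption; encryption never re-reads the
   gray originals, so the preprocessing step cannot leak the secret
   into a share.

The empirical counterpart is `share_uniformity`: Pearson chi-square of
observed pattern frequencies against uniform within each cover-level
stratum (dof = #patterns − 1, α = 0.01 in the shipped tests at 10,000
blocks, chosen to keep the flake rate negligible; strata under 50
blocks warn that the asymptotics are poor).  A deliberately degenerate
share (one pattern only) is rejected at p < 10⁻⁶.

## Quality metrics

* **Expansion factor** — share pixels / secret pixels: 4.0 for the
  classic schemes, 1.0 for EF-EVCS, by construction.
* **Contrast α** — (mean whites per recovered block over secret-white
  blocks − over secret-black blocks) / s_b: 1/2 for VCS, 1/4 for EVCS
  and EF-EVCS defaults.  Undefined (error) when the secret has one
  class only.
* **PSNR** is computed against the *limited-halftoned* secret rendered
  at block resolution, not the gray original: block-level recovery is
  the scheme's fidelity target, and the stack reproduces those levels
  exactly (PSNR = ∞), while tone lost to level restriction is visible
  when comparing the halftone itself to the original.

## Synthetic data

`make_fixture` generates the study inputs deterministically: gradients
(full tone sweep — exercises every level transition), checkerboards
(hard edges), text-like stroke images (sparse dark-on-white, a
document/annotation proxy), and blob images — dark elliptical clusters
with randomized radius, orientation and shade (intensity 20–90) on a
bright lightly-textured background (200–230), mimicking the first-order
statistics of stained tissue micrographs (dark nuclei, light stroma).
Default problem sizes are 64×64 for round-trip checks (1,024 blocks per
image, 100 secrets) and 200×200 (10,000 blocks) for the uniformity
tests — large enough for stable chi-square asymptotics while keeping
the full suite in a few seconds.

What the fixtures do **not** emulate: real modality noise, staining
variability, anatomical structure, or the downstream recognition
performance of models trained on recovered images.  Passing tests show
the scheme's combinatorial and statistical guarantees hold on any
grayscale input — they say nothing about diagnostic utility of
recovered images, which must be assessed on real data.

`degrade_dataset` mirrors the share-and-discard storage workflow over a
folder: per image, halftone → encrypt → stack → gray view, writing only
the four derived artifacts plus a JSON-lines manifest.  Per-image seeds
are derived by hashing the master seed with the image's relative path,
so adding files never perturbs existing outputs; the writer asserts no
output byte-duplicates an original.  Cover policy is either two fixed
fixture covers (default) or per-image generated covers; both are
exposed since real deployments may prefer either.

## Known limitations

* (2,2) only; no general (k,n) thresholds.
* Recovery is block-level and AND-based: contrast 1/4, output darker
  than the source; perfect gray-level recovery would need XOR-style
  stacking, which is out of scope.
* Supported formats are 8-bit grayscale PNG and raw PGM; color inputs
  are luminance-converted, DICOM and 16-bit depths are not read.
* The chi-square uniformity test is asymptotic; small images produce
  under-populated strata and a warning rather than a reliable p-value.
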