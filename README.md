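# vcshare

Visual cryptography for grayscale images, aimed at privacy-preserving
storage and transmission of medical images on low-power devices.  A
secret image is split into two *meaningful* shares — each looks like an
innocuous cover image — that reveal the secret only when superimposed.
Encryption and decryption are pure Boolean operations: no keys, no
arithmetic beyond a pixelwise AND, so shares can even be printed on
transparencies and stacked physically.  A hospital can store the two
shares on separate servers and discard the original; neither server
alone can reconstruct, or even statistically infer, the patient image.

## The schemes

All images use the convention **0 = black, 1 = white**, so stacking
transparencies is a pixelwise AND (black wins).

**Classic (2,2)-VCS / EVCS (baselines).**  Each secret pixel becomes an
m = 4 subpixel tile per share, built from an n×m basis matrix
`S^s_{c1 c2}` chosen by the secret pixel *s* (and cover pixels *c1, c2*
for the extended scheme) and randomized by a uniform column
permutation, e.g.

    S_bbb = [[0 1 0 0],    S_wbb = [[0 1 0 0],
             [1 0 0 0]]             [0 1 0 0]]

A share tile carries 3 black subpixels where its cover is black and 2
where it is white; the stack carries 4 black where the secret is black
and 3 where it is white.  Shares are four times the secret's area
(pixel expansion m = 4), contrast α = 1/4.

**Expansion-free EVCS (the core of the package).**  Instead of
expanding pixels, the secret and both covers are first *block-halftoned
with restricted gray levels*: every non-overlapping 2×2 block's
black-pixel count is quantized onto a candidate level set — {3, 4} for
the secret, {2, 3} for the covers.  Encryption then only *rearranges*
the pixels inside each cover block so that the two share blocks AND
together to exactly the secret block's level.  A block arrangement
(p1, p2) is valid for secret level t and cover levels b1, b2 iff

    max(b1, b2) ≤ t ≤ min(s_b, b1 + b2),      s_b = 4,

and the pair is drawn uniformly from all valid arrangements.  Shares
keep the covers' tone block-for-block, are **exactly the secret's
size** (expansion factor 1), and a single share's pattern distribution
is uniform within its cover level and independent of the secret — the
posterior that a secret block is black given one share stays at the
50% prior (proved by exact enumeration in `vcshare.metrics`, rational
arithmetic, no sampling).

## Worked example

```sh
vcshare fixture --kind blobs --size 128x128 --seed 7   --output secret.png
vcshare fixture --kind blobs --size 128x128 --seed 101 --output cover1.png
vcshare fixture --kind text  --size 128x128 --seed 202 --output cover2.png

vcshare encrypt --scheme ef-evcs --secret secret.png \
    --cover cover1.png --cover cover2.png --seed 5 --out-dir shares
vcshare stack shares/secret_share1.png shares/secret_share2.png --output recovered.png
vcshare view --input recovered.png --output recovered_gray.png
vcshare evaluate --secret secret.png \
    --share shares/secret_share1.png --share shares/secret_share2.png --seed 0
```

prints

```json
{
  "expansion": 1.0,
  "alpha": 0.25,
  "psnr": "inf",
  "leakage_max_deviation": 0.0,
  "uniformity_p": {
    "share1": { "2": 0.5026598303505191, "3": 0.6804202389414533 },
    "share2": { "2": 0.1619706688307037, "3": 0.5724067044708798 }
  }
}
```

Reading the numbers: the shares are the same size as the secret
(`expansion` 1.0); the recovered stack separates secret-white from
secret-black blocks by one white pixel per 2×2 block (`alpha` 0.25,
enough for the eye); the blocky gray view reconstructs the halftoned
secret's block levels exactly (`psnr` infinite against that reference);
no single-share pattern shifts the secret posterior off the 0.5 prior
(`leakage_max_deviation` 0.0); and within each cover level the share
patterns are statistically uniform (all chi-square p-values well above
0.01 — an attacker scanning a share sees only its cover).

`vcshare degrade --in DIR --out DIR --seed N` runs the whole
split/stack/view pipeline over an image folder and writes a JSON-lines
manifest for bit-exact replay, emulating the share-and-discard storage
workflow.

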