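# rubix — multi-resolution data fusion for diffusion MRI fibre orientations

Diffusion MRI acquisition is a bundle of trade-offs: higher spatial
resolution costs signal-to-noise, and higher angular contrast (larger
b-values, more gradient directions) costs it again.  When the same subject
has been scanned twice — once at high spatial resolution and once with
richer angular sampling at a coarser grid — neither dataset alone is
optimal.  `rubix` implements a Bayesian generative model that fits both
datasets *jointly* and estimates fibre orientation distributions on the
high-resolution (HR) grid, letting the angularly rich low-resolution (LR)
data constrain the HR solution.  It is aimed at researchers working with
paired multi-shell acquisitions (e.g. 3T/7T protocols) and at method
developers who need a fully synthetic, ground-truthed test bed for fusion
inference.

## The model

Within one HR voxel the signal at measurement point $(b_k, \mathbf{g}_k)$ is
a partial-volume mixture of an isotropic "ball" and up to $N$ fibre
compartments (parametric spherical deconvolution with a delta-function
fODF):

$$S_k = S_0\Big[\big(1-\textstyle\sum_n f_n\big)
\Big(\tfrac{\beta}{\beta+b_k}\Big)^{\alpha}
+\sum_{n=1}^{N} f_n \exp\big(-b_k\tfrac{3\lambda_m}{2\lambda_R+1}
[(1-\lambda_R)(\mathbf{g}_k\cdot\mathbf{v}_n)^2+\lambda_R]\big)\Big]$$

with a Gamma distribution of isotropic diffusivities
($\beta=d_m/d_{std}^2$, $\alpha=d_m\beta$) and an axially symmetric
single-fibre kernel with mean eigenvalue $\lambda_m=d_m$ and radial/axial
ratio $\lambda_R$.  An LR voxel intersecting $P$ HR voxels with fractions
$a_p$ is predicted by a signal-weighted ratio:

$$\frac{S_l^{LR}}{S_0^{LR}}
=\frac{\sum_p a_p S_{l,p}^{HR}}{\sum_p a_p S_{0,p}^{HR}},$$

evaluated at the LR gradient table — which may differ from the HR table in
both b-values and directions.  Both datasets enter a joint Rician
likelihood with separate noise precisions, and inference is Metropolis
MCMC per LR neighborhood.  Sparsity of the fODF is controlled by an
automatic relevance determination (ARD) prior $p(f_n)\propto 1/f_n^{w}$
($n\ge 2$), and the orientations in a neighborhood share a mixture-of-Watson
hyperprior whose modes and concentrations are estimated on the fly — this
is the channel through which the LR angular information constrains the HR
grid.

The package also provides: the single-dataset voxel-wise fit, posterior
metrics (crossing-fibre counts at the $f>5\%$ threshold and 95% cones of
uncertainty), response-prior learning from coherent white matter
($\lambda_R=(\lambda_2+\lambda_3)/2\lambda_1$ from DTI eigenvalues), and a
synthetic paired-phantom generator with Rician noise at controllable SNR.

## Worked example

```bash
python examples/03_voxelwise_fit.py
```

```
retained draws per parameter: 50
posterior mean fractions:     [0.68  0.    0.001]
true f: (0.7, 0, 0) — the ARD prior shrinks the unused compartments
orientation error:            0.46 deg
posterior mean d_m:           1.01e-03  (true 1.0e-03)
95% cone of uncertainty:      1.19 deg
```

One single-fibre voxel at SNR 30 under a 3-shell, 90-direction protocol:
the posterior mean orientation lands within half a degree of the truth, the
anisotropic volume fraction (0.68 vs 0.7) and diffusivity (1% off) are
recovered, and the two unsupported compartments are switched off by the ARD
prior.  `examples/04_fusion_fit.py` runs the fusion comparison: on a noisy
HR dataset (SNR 15) paired with a clean, angularly rich LR dataset, the
joint fit shrinks the mean 95% cone of uncertainty from ~10° to ~3° while
keeping estimates on the HR grid.  The other examples cover the forward
model, the phantom generator and response-prior learning.

A thin CLI wraps the same functions for shell use:

```bash
rubix simulate --kind crossing90 --grid 6,6,6 --out-dir sim/
rubix fit-rubix --hr-data sim/hr_data.nii.gz ... --out-dir fit/
rubix metrics --dir fit/ --out metrics.csv
rubix config show
```

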