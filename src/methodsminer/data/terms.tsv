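# Statistical-term standardization: variant<TAB>canonical (singular, hyphenated).
# Variants are matched as 1-3 token n-grams, longest match first; every
# canonical form also maps to itself at load time.
chi square	chi-square
chi squares	chi-square
chi-squares	chi-square
chisquare	chi-square
chisquares	chi-square
chi squared	chi-square
chi-squared	chi-square
chisquared	chi-square
t test	t-test
t tests	t-test
t-tests	t-test
ttest	t-test
ttests	t-test
z test	z-test
z-tests	z-test
f test	f-test
f-tests	f-test
u test	u-test
p value	p-value
p values	p-value
p-values	p-value
pvalue	p-value
pvalues	p-value
q value	q-value
q-values	q-value
analysis of variance	anova
analyses of variance	anova
analysis variance	anova
analyses variance	anova
anovas	anova
analysis of covariance	ancova
analysis covariance	ancova
ancovas	ancova
one way	one-way
oneway	one-way
two way	two-way
twoway	two-way
three way	three-way
post hoc	post-hoc
posthoc	post-hoc
wilcoxon rank sum	wilcoxon-rank-sum
wilcoxon rank-sum	wilcoxon-rank-sum
wilcoxon ranksum	wilcoxon-rank-sum
wilcoxon signed rank	wilcoxon-signed-rank
wilcoxon signed-rank	wilcoxon-signed-rank
rank sum	rank-sum
rank sums	rank-sum
signed rank	signed-rank
mann whitney	mann-whitney
mannwhitney	mann-whitney
mann-whitney u	mann-whitney
kruskal wallis	kruskal-wallis
kruskalwallis	kruskal-wallis
hosmer lemeshow	hosmer-lemeshow
hosmerlemeshow	hosmer-lemeshow
kaplan meier	kaplan-meier
kaplanmeier	kaplan-meier
log rank	log-rank
logrank	log-rank
fisher exact	fisher-exact
fishers exact	fisher-exact
shapiro wilk	shapiro-wilk
shapirowilk	shapiro-wilk
kolmogorov smirnov	kolmogorov-smirnov
kolmogorovsmirnov	kolmogorov-smirnov
anderson darling	anderson-darling
bland altman	bland-altman
blandaltman	bland-altman
cochran armitage	cochran-armitage
benjamini hochberg	benjamini-hochberg
tukey hsd	tukey-hsd
dunnett test	dunnett-test
mixed model	mixed-model
mixed models	mixed-model
mixed-models	mixed-model
mixed effects	mixed-effects
mixed effect	mixed-effects
random effects	random-effects
random effect	random-effects
fixed effects	fixed-effects
fixed effect	fixed-effects
proportional hazards	proportional-hazards
proportional hazard	proportional-hazards
odds ratio	odds-ratio
odds ratios	odds-ratio
hazard ratio	hazard-ratio
hazard ratios	hazard-ratio
risk ratio	risk-ratio
risk ratios	risk-ratio
relative risk	relative-risk
relative risks	relative-risk
intention to treat	intention-to-treat
intention treat	intention-to-treat
per protocol	per-protocol
goodness of fit	goodness-of-fit
goodness fit	goodness-of-fit
repeated measures	repeated-measures
repeated measure	repeated-measures
receiver operating characteristic	roc
generalized estimating equations	gee
generalized estimating equation	gee
least squares	least-squares
least square	least-squares
sum of squares	sum-of-squares
sum squares	sum-of-squares
standard deviation	standard-deviation
standard deviations	standard-deviation
standard error	standard-error
standard errors	standard-error
interquartile range	inter-quartile-range
inter-quartile range	inter-quartile-range
inter quartile range	inter-quartile-range
confidence intervals	confidence-interval
confidence interval	confidence-interval
credible interval	credible-interval
credible intervals	credible-interval
effect size	effect-size
effect sizes	effect-size
drop out	drop-out
follow up	follow-up
followup	follow-up
meta analysis	meta-analysis
metaanalysis	meta-analysis
meta analyses	meta-analysis
cross validation	cross-validation
crossvalidation	cross-validation
non parametric	non-parametric
nonparametric	non-parametric
non normal	non-normal
nonnormal	non-normal
log transformed	log-transformed
graphpad prism	graphpad-prism
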