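# Independent oracle for the 2x2x2 mixed repeated-measures ANOVA.
# Generates the same fixed dataset as tests/test_normative.py (frozen
# there) and prints the aov() multi-stratum F tests plus partial eta
# squared as JSON.  Balanced design, so type-I/III distinctions vanish.
library(jsonlite)
d <- read.csv("anova_fixture.csv")
d$subject_id <- factor(d$subject_id)
d$group <- factor(d$group)
d$viewing <- factor(d$viewing)
d$side <- factor(d$side)
fit <- aov(score ~ group * viewing * side + Error(subject_id / (viewing * side)), data = d)
s <- summary(fit)
out <- list()
for (stratum in s) {
  tab <- stratum[[1]]
  for (i in seq_len(nrow(tab))) {
    nm <- trimws(rownames(tab)[i])
    if (nm == "Residuals") next
    resid_row <- which(trimws(rownames(tab)) == "Residuals")
    out[[tolower(gsub("group:","group:",nm))]] <- list(
      F = tab[i, "F value"],
      df1 = tab[i, "Df"],
      df2 = tab[resid_row, "Df"],
      p = tab[i, "Pr(>F)"],
      eta_p2 = tab[i, "Sum Sq"] / (tab[i, "Sum Sq"] + tab[resid_row, "Sum Sq"])
    )
  }
}
cat(toJSON(out, digits = 10, auto_unbox = TRUE))
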