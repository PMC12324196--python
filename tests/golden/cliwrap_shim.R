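# Shared runtime shim for generated wrappers (standalone, base R only).
#
# A runner is an environment with new_execution(metadata); an execution is an
# environment with translate_input(path), output_root() and run(cargs).
# cliwrap_dry_runner() records argv and never spawns a process.

fmt_value <- function(v) {
  if (is.logical(v)) stop("booleans are flag-only")
  if (is.numeric(v)) {
    if (is.finite(v) && v == floor(v) && abs(v) < 1e15) {
      return(sprintf("%.0f", v))
    }
    return(format(v, trim = TRUE, scientific = NA))
  }
  as.character(v)
}

join_path <- function(...) {
  paste(..., sep = "/")
}

cliwrap_strip_suffix <- function(name, suffixes) {
  best <- ""
  for (s in suffixes) {
    if (endsWith(name, s) && nchar(s) > nchar(best)) best <- s
  }
  if (nchar(best) > 0) substr(name, 1, nchar(name) - nchar(best)) else name
}

template_part <- function(value, is_file, strip) {
  s <- fmt_value(value)
  if (is_file) s <- basename(s)
  cliwrap_strip_suffix(s, strip)
}

cliwrap_dry_runner <- function() {
  self <- new.env()
  self$records <- list()
  self$last_cargs <- NULL
  self$seq <- 0L
  self$new_execution <- function(metadata) {
    self$seq <- self$seq + 1L
    seq_now <- self$seq
    ex <- new.env()
    ex$translate_input <- function(path) path
    ex$output_root <- function() {
      paste0(metadata[["uid"]], "_", seq_now)
    }
    ex$run <- function(cargs) {
      self$last_cargs <- as.character(cargs)
      self$records[[length(self$records) + 1L]] <- list(
        seq = seq_now, uid = metadata[["uid"]], cargs = as.character(cargs))
      invisible(0L)
    }
    ex
  }
  self
}

default_runner <- function() {
  cliwrap_dry_runner()
}
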