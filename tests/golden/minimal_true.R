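# true — generated wrapper, do not edit.

# Generated interface. source() cliwrap_shim.R before this file.


MINIMAL_TRUE_METADATA <- list("uid" = "minimal_true", "name" = "true", "container_image" = NULL)


#' true (minimal_true).
#' Smallest valid interface: a bare executable, no parameters, no outputs.
#'
#' runner: execution adapter; defaults to the dry runner
#' Returns a record of resolved output paths (root only).
#'
minimal_true <- function(runner = NULL) {
  if (is.null(runner)) runner <- default_runner()
  execution <- runner$new_execution(MINIMAL_TRUE_METADATA)
  cargs <- character(0)
  cargs <- c(cargs, "true")
  root_ <- execution$output_root()
  ret_ <- list(root = root_)
  execution$run(cargs)
  return(ret_)
}
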