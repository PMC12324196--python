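# toycalc — generated wrapper, do not edit.

# Generated interface. source() cliwrap_shim.R before this file.


TOYCALC_METADATA <- list("uid" = "toycalc", "name" = "toycalc", "container_image" = NULL)


#' Construct the 'add' alternative for ops.
#' value: Constant to add (float)
#'
toycalc_ops_add <- function(value) {
  return(list("__tag" = "add", "value" = value))
}


#' Construct the 'sub' alternative for ops.
#' value: Constant to subtract (float)
#'
toycalc_ops_sub <- function(value) {
  return(list("__tag" = "sub", "value" = value))
}


#' Construct the 'option1' alternative for ops/complex/mode.
#' param1: no documentation (string)
#'
toycalc_ops_complex_mode_option1 <- function(param1) {
  return(list("__tag" = "option1", "param1" = param1))
}


#' Construct the 'option2' alternative for ops/complex/mode.
#' param1: no documentation (string)
#' param2: no documentation (string)
#'
toycalc_ops_complex_mode_option2 <- function(param1, param2) {
  return(list("__tag" = "option2", "param1" = param1, "param2" = param2))
}


#' Construct the 'complex' alternative for ops.
#' mode: Operation mode (union)
#'
toycalc_ops_complex <- function(mode) {
  return(list("__tag" = "complex", "mode" = mode))
}


#' Build argv fragment for ops/complex/mode.
#'
toycalc_ops_complex_mode_cargs_ <- function(item, execution) {
  cargs <- character(0)
  tag_ <- item[["__tag"]]
  if (tag_ == "option1") {
    v_param1_ <- item[["param1"]]
    cargs <- c(cargs, "option1")
    cargs <- c(cargs, fmt_value(v_param1_))
  } else if (tag_ == "option2") {
    v_param1_ <- item[["param1"]]
    v_param2_ <- item[["param2"]]
    cargs <- c(cargs, "option2")
    cargs <- c(cargs, fmt_value(v_param1_))
    cargs <- c(cargs, fmt_value(v_param2_))
  }
  return(cargs)
}


#' Build argv fragment for ops.
#'
toycalc_ops_cargs_ <- function(item, execution) {
  cargs <- character(0)
  tag_ <- item[["__tag"]]
  if (tag_ == "add") {
    v_value_ <- item[["value"]]
    cargs <- c(cargs, "-add")
    cargs <- c(cargs, fmt_value(v_value_))
  } else if (tag_ == "sub") {
    v_value_ <- item[["value"]]
    cargs <- c(cargs, "-sub")
    cargs <- c(cargs, fmt_value(v_value_))
  } else if (tag_ == "complex") {
    v_mode_ <- item[["mode"]]
    cargs <- c(cargs, "-complex")
    cargs <- c(cargs, toycalc_ops_complex_mode_cargs_(v_mode_, execution))
  }
  return(cargs)
}


#' toycalc (toycalc).
#' Toy image calculator: an input file, zero or more chained operations (each with its own parameters), and an output. Operation order is significant.
#'
#' input: Input image (file)
#' ops: Operation chain; emitted in the order supplied (union; repeatable; optional)
#' output: Output image name (string)
#' runner: execution adapter; defaults to the dry runner
#' Returns a record of resolved output paths (out_file).
#'
toycalc <- function(input, output, ops = NULL, runner = NULL) {
  if (is.null(runner)) runner <- default_runner()
  execution <- runner$new_execution(TOYCALC_METADATA)
  cargs <- character(0)
  cargs <- c(cargs, "toycalc")
  cargs <- c(cargs, execution$translate_input(input))
  if ((!is.null(ops) && length(ops) > 0)) {
    for (it1_ in ops) {
      cargs <- c(cargs, toycalc_ops_cargs_(it1_, execution))
    }
  }
  cargs <- c(cargs, fmt_value(output))
  root_ <- execution$output_root()
  ret_ <- list(root = root_, out_file = join_path(root_, template_part(output, FALSE, c())))
  execution$run(cargs)
  return(ret_)
}
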