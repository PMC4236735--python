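"""Conversion between sympy expressions and SBML math (ASTNode / L3 formula).

Only the operator subset the generated rate laws use is supported:
+ - * / ^, ln, log10, exp, names and numeric literals. That subset is also
what is accepted when reading kinetic laws back from SBML.
"""
from __future__ import annotations

import libsbml
import sympy
from sympy.printing.str import StrPrinter
from sympy.printing.precedence import precedence

from .errors import SBMLReadError


class _L3FormulaPrinter(StrPrinter):
    """Print sympy expressions in SBML L3 infix (``^`` power, ``ln`` log)."""

    def _print_Pow(self, expr, rational=False):
        prec = precedence(expr)
        base = self.parenthesize(expr.base, prec, strict=False)
        exp = self.parenthesize(expr.exp, prec, strict=False)
        return f"{base}^{exp}"

    def _print_log(self, expr):
        return f"ln({self._print(expr.args[0])})"

    def _print_exp(self, expr):
        return f"exp({self._print(expr.args[0])})"


_printer = _L3FormulaPrinter()


def sympy_to_ast(expr: sympy.Expr) -> libsbml.ASTNode:
    """Convert a sympy expression into a libsbml ASTNode."""
    formula = _printer.doprint(sympy.nsimplify(expr, rational=False))
    node = libsbml.parseL3Formula(formula)
    if node is None:
        raise ValueError(
            f"could not encode rate expression as SBML math: {formula!r}"
        )
    return node


_BINARY = {
    libsbml.AST_PLUS: lambda args: sympy.Add(*args),
    libsbml.AST_TIMES: lambda args: sympy.Mul(*args),
}


def ast_to_sympy(node: libsbml.ASTNode) -> sympy.Expr:
    """Convert a libsbml ASTNode back into a sympy expression."""
    t = node.getType()
    children = [ast_to_sympy(node.getChild(i)) for i in range(node.getNumChildren())]
    if t in _BINARY:
        return _BINARY[t](children)
    if t == libsbml.AST_MINUS:
        if len(children) == 1:
            return -children[0]
        return children[0] - children[1]
    if t == libsbml.AST_DIVIDE:
        return children[0] / children[1]
    if t in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
        return children[0] ** children[1]
    if t == libsbml.AST_FUNCTION_LN:
        return sympy.log(children[0])
    if t == libsbml.AST_FUNCTION_LOG:
        # SBML log(x) is base-10 unless an explicit base child is present.
        if len(children) == 2:
            return sympy.log(children[1]) / sympy.log(children[0])
        return sympy.log(children[0]) / sympy.log(10)
    if t == libsbml.AST_FUNCTION_EXP:
        return sympy.exp(children[0])
    if t == libsbml.AST_FUNCTION_ROOT:
        if len(children) == 2:
            return children[1] ** (1 / children[0])
        return sympy.sqrt(children[0])
    if t == libsbml.AST_NAME:
        return sympy.Symbol(node.getName())
    if t == libsbml.AST_INTEGER:
        return sympy.Integer(node.getInteger())
    if t in (libsbml.AST_REAL, libsbml.AST_REAL_E):
        return sympy.Float(node.getReal())
    if t == libsbml.AST_RATIONAL:
        return sympy.Rational(node.getNumerator(), node.getDenominator())
    if t == libsbml.AST_CONSTANT_E:
        return sympy.E
    if t == libsbml.AST_CONSTANT_PI:
        return sympy.pi
    raise SBMLReadError(
        f"unsupported math construct in kinetic law (AST type {t})"
    )
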